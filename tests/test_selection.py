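import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natfert.selection import (
    EHHCurve,
    HaplotypePanel,
    ehh,
    empirical_percentile,
    ihh,
    ihs_unstandardized,
    read_hap_legend,
    standardize_ihs,
    weir_cockerham_theta,
    weir_cockerham_theta_genotypic,
)
from natfert.simulate import SweepPanelConfig, simulate_sweep_panel


def wc_theta_oracle(n1, x1, n2, x2):
    """Independent transcription of the haploid ANOVA estimator, written
    as explicit sums-of-squares (no shared code with the implementation)."""
    counts = [(n1, x1), (n2, x2)]
    p_bar = (x1 + x2) / (n1 + n2)
    ss_among = sum(n * (x / n - p_bar) ** 2 for n, x in counts)
    msp = ss_among / (2 - 1)
    ss_within = sum(n * (x / n) * (1 - x / n) for n, x in counts)
    msg = ss_within / ((n1 - 1) + (n2 - 1))
    n_c = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    return (msp - msg) / (msp + (n_c - 1) * msg)


class TestWeirCockerham:
    def test_no_differentiation_near_zero(self):
        r = weir_cockerham_theta(120, 60, 120, 60)
        assert abs(r.theta) < 0.01  # unbiased estimator: -1/(n_c - 1)

    def test_fixation_limit(self):
        r = weir_cockerham_theta(10_000, 10_000, 10_000, 0)
        assert r.theta == pytest.approx(1.0, abs=1e-3)

    def test_matches_independent_transcription(self):
        r = weir_cockerham_theta(100, 80, 100, 20)
        assert r.theta == pytest.approx(wc_theta_oracle(100, 80, 100, 20),
                                        rel=1e-12)

    def test_both_monomorphic_undefined(self):
        r = weir_cockerham_theta(50, 0, 60, 0)
        assert r.undefined and np.isnan(r.theta)

    def test_minimal_sample(self):
        r = weir_cockerham_theta(2, 1, 2, 0)
        assert np.isfinite(r.theta)

    @settings(derandomize=True, max_examples=100)
    @given(
        n1=st.integers(2, 300), n2=st.integers(2, 300),
        f1=st.floats(0, 1), f2=st.floats(0, 1),
    )
    def test_symmetries(self, n1, n2, f1, f2):
        x1, x2 = round(f1 * n1), round(f2 * n2)
        a = weir_cockerham_theta(n1, x1, n2, x2)
        b = weir_cockerham_theta(n2, x2, n1, x1)  # population order
        c = weir_cockerham_theta(n1, n1 - x1, n2, n2 - x2)  # allele labels
        if a.undefined:
            assert b.undefined and c.undefined
        else:
            assert a.theta == pytest.approx(b.theta, rel=1e-9, abs=1e-12)
            assert a.theta == pytest.approx(c.theta, rel=1e-9, abs=1e-12)

    def test_genotypic_variant_tracks_allele_variant_under_hwe(self):
        # HWE genotype counts at p=0.8 / 0.2
        r_g = weir_cockerham_theta_genotypic(100, (64, 32, 4), 100, (4, 32, 64))
        r_a = weir_cockerham_theta(200, 160, 200, 40)
        assert r_g.method == "genotypic"
        assert r_g.theta == pytest.approx(r_a.theta, abs=0.05)


def brute_force_ehh(panel, core_allele, direction):
    """O(n^2) all-pairs shared-prefix EHH (test oracle)."""
    H = panel.haplotypes
    carriers = np.flatnonzero(H[:, panel.core_index] == core_allele)
    cols = (
        range(panel.core_index + 1, H.shape[1])
        if direction == "downstream"
        else range(panel.core_index - 1, -1, -1)
    )
    n = carriers.size
    out = [1.0]
    dists = [0.0]
    span: list[int] = []
    for j in cols:
        span.append(j)
        same = 0
        for a in range(n):
            for b in range(a + 1, n):
                if all(
                    H[carriers[a], k] == H[carriers[b], k] for k in span
                ):
                    same += 1
        out.append(same / (n * (n - 1) / 2))
        dists.append(abs(panel.positions[j] - panel.positions[panel.core_index]))
    return np.array(dists), np.array(out)


class TestEHH:
    def small_panel(self, rows, core=2):
        H = np.array(rows)
        return HaplotypePanel(H, np.arange(H.shape[1]) * 1000.0, core)

    def test_core_value_is_one(self):
        p = self.small_panel([[0, 1, 1, 1, 0]] * 3 + [[0, 0, 0, 0, 0]])
        c = ehh(p, 1, "downstream")
        assert c.ehh[0] == 1.0

    def test_all_distinct_at_first_flank(self):
        # 4 carriers, all four 2-SNP flanking patterns distinct -> EHH 0
        p = self.small_panel(
            [[0, 0, 1, 0, 0], [0, 1, 1, 0, 1], [1, 0, 1, 1, 0], [1, 1, 1, 1, 1]]
        )
        c = ehh(p, 1, "downstream")
        assert c.ehh[1] == pytest.approx(2 / 6)  # {0,1} split 2-2 at first SNP
        assert c.ehh[2] == 0.0

    def test_two_identical_pairs(self):
        p = self.small_panel(
            [[0, 0, 1, 0, 0], [0, 0, 1, 0, 0], [1, 1, 1, 1, 1], [1, 1, 1, 1, 1]]
        )
        for d in ("upstream", "downstream"):
            c = ehh(p, 1, d)
            assert np.allclose(c.ehh, [1.0, (1 + 1) / 6, (1 + 1) / 6])

    def test_monotone_and_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(24, 15))
        H[:, 7] = (np.arange(24) < 10).astype(int)
        p = HaplotypePanel(H, np.sort(rng.choice(10**6, 15, replace=False)).astype(float), 7)
        for allele in (0, 1):
            for d in ("upstream", "downstream"):
                c = ehh(p, allele, d)
                assert np.all(np.diff(c.ehh) <= 1e-12)
                bd, bv = brute_force_ehh(p, allele, d)
                assert np.allclose(c.distances, bd)
                assert np.allclose(c.ehh, bv)

    def test_needs_two_carriers(self):
        p = self.small_panel([[0, 0, 1, 0, 0], [0, 0, 0, 0, 0]])
        with pytest.raises(ValueError):
            ehh(p, 1, "downstream")


class TestIHH:
    def curve(self, dists, vals, direction="downstream"):
        return EHHCurve(direction, np.array(dists, float), np.array(vals, float))

    def test_rectangle(self):
        up = self.curve([0, 50_000], [1, 1], "upstream")
        down = self.curve([0, 50_000], [1, 1])
        area, edge = ihh(up, down)
        assert area == pytest.approx(100_000)
        assert edge  # never dropped below the cutoff inside the panel

    def test_single_trapezoid(self):
        up = self.curve([0, 1000], [1, 0], "upstream")
        down = self.curve([0, 2000], [1, 0])
        area, edge = ihh(up, down)
        assert area == pytest.approx(0.5 * 1000 + 0.5 * 2000)
        assert not edge

    def test_halving_cutoff_never_decreases_area(self):
        rng = np.random.default_rng(1)
        vals = np.sort(rng.random(30))[::-1]
        vals[0] = 1.0
        up = self.curve(np.arange(30) * 500.0, vals, "upstream")
        down = self.curve(np.arange(30) * 500.0, vals)
        a1, _ = ihh(up, down, cutoff=0.2)
        a2, _ = ihh(up, down, cutoff=0.1)
        assert a2 >= a1 - 1e-12


class TestIHS:
    def test_label_swap_antisymmetry(self):
        panel, _ = simulate_sweep_panel(SweepPanelConfig(seed=3))
        u1 = ihs_unstandardized(panel)
        flipped = HaplotypePanel(
            1 - panel.haplotypes, panel.positions, panel.core_index
        )
        u2 = ihs_unstandardized(flipped)
        assert u1.uihs == pytest.approx(-u2.uihs, rel=1e-9)

    def test_swept_panel_negative(self):
        panel, truth = simulate_sweep_panel(SweepPanelConfig(seed=12))
        r = ihs_unstandardized(panel)
        assert r.uihs < 0  # derived background carries the long haplotypes

    def test_noise_free_sweep_has_flat_derived_ehh(self):
        cfg = SweepPanelConfig(seed=4, mutation_noise_per_site=0.0,
                               n_hap=40, n_snp=201, sweep_tract_bp=100_000)
        panel, truth = simulate_sweep_panel(cfg)
        c = ehh(panel, 1, "downstream")
        inside = c.distances <= cfg.sweep_tract_bp / 2
        assert np.all(c.ehh[inside] == 1.0)


class TestStandardize:
    def test_single_bin_is_global_zscore(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=200)
        f = np.full(200, 0.42)
        z, bins, merges = standardize_ihs(u, f, bins=20)
        assert np.allclose(z, (u - u.mean()) / u.std())
        assert len(set(bins.tolist())) == 1

    def test_per_bin_moments(self):
        rng = np.random.default_rng(6)
        u = rng.normal(size=2000)
        f = rng.uniform(0.01, 0.99, 2000)
        z, bins, merges = standardize_ihs(u, f, bins=20)
        for b in set(bins.tolist()):
            sel = bins == b
            assert abs(z[sel].mean()) < 1e-9
            assert z[sel].std() == pytest.approx(1.0, abs=1e-9)

    def test_undersized_bin_merged(self):
        u = np.array([0.1, -0.2, 0.5, 1.4, 0.9])
        f = np.array([0.11, 0.12, 0.13, 0.14, 0.91])  # one lonely value
        z, bins, merges = standardize_ihs(u, f, bins=10)
        assert merges and merges[0][0] == 9
        assert len(set(bins.tolist())) == 1

    def test_constant_bin_degenerate(self):
        u = np.array([1.0, 1.0, 1.0])
        f = np.array([0.2, 0.2, 0.2])
        with pytest.raises(ValueError):
            standardize_ihs(u, f, bins=10)


class TestEmpiricalPercentile:
    def test_median_threshold(self):
        x = np.linspace(-3, 3, 10_001)
        out = empirical_percentile(x, x, 0.0, 0.0)
        assert out["fst_tail"] == pytest.approx(0.5, abs=1e-3)
        assert out["ihs_tail"] == pytest.approx(0.5, abs=1e-3)

    def test_beyond_extremes_reported_below_resolution(self):
        out = empirical_percentile([0.1, 0.2], [-1.0, -2.0], 0.9, -5.0)
        assert out["fst_tail"] == 0.0 and out["fst_tail_lt_one_over_n"]
        assert out["ihs_tail"] == 0.0 and out["ihs_tail_lt_one_over_n"]

    def test_planted_joint_tail_recovered_exactly(self):
        """10^5 (fst, ihs) pairs with exactly 300 jointly extreme ones:
        the joint fraction comes back as 0.003."""
        rng = np.random.default_rng(7)
        n = 100_000
        fst = rng.uniform(0, 0.4, n)
        ihs = rng.uniform(-1.8, 2.0, n)
        idx = rng.choice(n, 300, replace=False)
        fst[idx] = rng.uniform(0.43, 0.9, 300)
        ihs[idx] = rng.uniform(-4.0, -1.93, 300)
        out = empirical_percentile(fst, ihs, 0.43, -1.93)
        assert out["joint_tail"] == pytest.approx(0.003, abs=1e-12)


def test_hap_legend_roundtrip(tmp_path):
    panel, _ = simulate_sweep_panel(
        SweepPanelConfig(seed=9, n_hap=10, n_snp=21, sweep_tract_bp=5000)
    )
    hap = tmp_path / "p.hap"
    legend = tmp_path / "p.legend"
    np.savetxt(hap, panel.haplotypes.T, fmt="%d")
    with open(legend, "w") as fh:
        fh.write("id position allele0 allele1\n")
        for j, pos in enumerate(panel.positions):
            fh.write(f"snp{j} {pos:.0f} A G\n")
    back = read_hap_legend(hap, legend, core_index=panel.core_index)
    assert np.array_equal(back.haplotypes, panel.haplotypes)
    assert np.array_equal(back.positions, panel.positions)


def test_hap_legend_ancestral_recode(tmp_path):
    hap = tmp_path / "p.hap"
    legend = tmp_path / "p.legend"
    hap.write_text("0 1\n1 1\n")
    legend.write_text(
        "id position allele0 allele1 ancestral\n"
        "s1 100 A G A\n"
        "s2 200 C T T\n"  # ALT is ancestral: recode
    )
    p = read_hap_legend(hap, legend, core_index=0)
    assert np.array_equal(p.haplotypes[:, 0], [0, 1])
    assert np.array_equal(p.haplotypes[:, 1], [0, 0])
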