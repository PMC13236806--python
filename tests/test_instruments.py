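"""Genotype QC, cis-meQTL windows, LD clumping, F statistics and the screen."""

import math

import numpy as np
import pandas as pd
import pytest

from meqtlmr.datamodel import GenotypeMatrix, MethylationMatrix
from meqtlmr.instruments import (
    Clump,
    clump,
    cumulative_f,
    hwe_exact,
    ld_r2,
    map_cis_meqtls,
    qc_variants,
    screen_instruments,
)


def _hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force exact HWE: enumerate all het counts, multinomial weights."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    common = 2 * n - rare

    def log_prob(het):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
            + math.lgamma(rare + 1)
            + math.lgamma(common + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets if (rare - h) // 2 <= n - h}
    total = sum(probs.values())
    obs = probs[n_ab]
    return min(sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total, 1.0)


class TestHweExact:
    def test_perfect_hwe_proportions(self):
        assert hwe_exact(25, 50, 25) == pytest.approx(1.0)

    def test_all_heterozygotes_extreme(self):
        assert hwe_exact(0, 100, 0) <= 1e-6

    @pytest.mark.parametrize(
        "counts", [(10, 20, 10), (50, 10, 2), (0, 5, 95), (7, 0, 3), (1, 1, 1)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)

    def test_random_counts_match_oracle(self, rng):
        for _ in range(100):
            c = rng.integers(0, 60, 3)
            assert hwe_exact(*c) == pytest.approx(_hwe_oracle(*c), rel=1e-9)


def _geno(dosages, positions=None, info=None):
    dosages = pd.DataFrame(dosages)
    dosages.index = [f"s{i}" for i in range(len(dosages))]
    dosages.columns = [f"v{j}" for j in range(dosages.shape[1])]
    m = dosages.shape[1]
    ann = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
            "ref_allele": "A",
            "alt_allele": "G",
            "info_score": info if info is not None else np.ones(m),
        },
        index=pd.Index(dosages.columns, name="variant_id"),
    )
    return GenotypeMatrix(dosages, ann)


class TestQcVariants:
    def test_low_maf_removed(self, rng):
        d = np.column_stack(
            [rng.binomial(2, 0.005, 2000), rng.binomial(2, 0.3, 2000)]
        ).astype(float)
        G = _geno(d)
        filtered, counts = qc_variants(G)
        assert counts["maf"] >= 1
        assert "v1" in filtered.dosages.columns
        assert "v0" not in filtered.dosages.columns

    def test_hwe_violation_removed(self, rng):
        d = np.column_stack(
            [np.ones(200), rng.binomial(2, 0.3, 200)]
        ).astype(float)  # v0: every sample heterozygous
        filtered, counts = qc_variants(_geno(d))
        assert counts["hwe"] == 1
        assert "v0" not in filtered.dosages.columns

    def test_missingness_removed(self, rng):
        d = rng.binomial(2, 0.3, (100, 2)).astype(float)
        d[:10, 0] = np.nan  # 10% missing
        filtered, counts = qc_variants(_geno(d))
        assert counts["missingness"] == 1
        assert "v0" not in filtered.dosages.columns

    def test_low_info_removed(self, rng):
        d = rng.binomial(2, 0.3, (100, 2)).astype(float)
        filtered, counts = qc_variants(_geno(d, info=[0.5, 0.95]))
        assert counts["info"] == 1
        assert list(filtered.dosages.columns) == ["v1"]


class TestLdR2:
    def test_identical_columns(self, rng):
        d = rng.binomial(2, 0.3, (100, 1)).astype(float)
        G = _geno(np.column_stack([d, d]))
        assert ld_r2(G, "v0", "v1") == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0, 2, 0, 2, 0, 2], dtype=float)
        assert ld_r2(_geno(np.column_stack([x, y])), "v0", "v1") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_covariance_formula(self, rng):
        for _ in range(20):
            d = rng.binomial(2, 0.3, (50, 2)).astype(float)
            G = _geno(d)
            cov = np.cov(d.T)
            expected = cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1])
            assert ld_r2(G, "v0", "v1") == pytest.approx(expected, abs=1e-12)


def _correlated_columns(rng, n, r):
    """Two [0,2]-valued columns with exact sample correlation r."""
    z1 = rng.normal(0, 1, n)
    z2 = rng.normal(0, 1, n)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = z2 - z2.mean()
    z2 -= z1 * (z1 @ z2) / n  # orthogonalise
    z2 /= z2.std()
    y = r * z1 + np.sqrt(1 - r**2) * z2
    scale = lambda v: (v - v.min()) / (v.max() - v.min()) * 2.0
    return scale(z1), scale(y)


def _clump_oracle(pvals, r2, threshold):
    """Independent exhaustive greedy: explicit loop over a p-sorted worklist."""
    order = sorted(range(len(pvals)), key=lambda i: (pvals[i], i))
    assigned = set()
    clumps = []
    for i in order:
        if i in assigned:
            continue
        members = [i] + [
            j for j in order if j not in assigned and j != i and r2[i][j] >= threshold
        ]
        assigned.update(members)
        clumps.append((i, members))
    return clumps


class TestClump:
    def _random_panel(self, rng, m):
        """Dosage columns with a random (factor-model) correlation pattern."""
        n = 400
        A = rng.normal(0, 1, (m, max(1, m // 2)))
        z = rng.normal(0, 1, (n, A.shape[1])) @ A.T + 0.5 * rng.normal(0, 1, (n, m))
        d = (z - z.min(axis=0)) / (z.max(axis=0) - z.min(axis=0)) * 2
        return _geno(d)

    def test_three_snp_worked_example(self, rng):
        # r2(1,2)=0.5, r2(1,3)=0.05, r2(2,3)=0.02 with p = 1e-8, 1e-5, 1e-3
        x1, x2 = _correlated_columns(rng, 500, np.sqrt(0.5))
        z = rng.normal(0, 1, 500)
        # make v2 nearly independent of both
        for other in (x1, x2):
            oc = other - other.mean()
            z -= oc * (oc @ z) / (oc @ oc)
        x3 = (z - z.min()) / (z.max() - z.min()) * 2
        G = _geno(np.column_stack([x1, x2, x3]))
        assert ld_r2(G, "v0", "v1") > 0.4
        assert ld_r2(G, "v0", "v2") < 0.01
        assoc = pd.DataFrame(
            {"variant_id": ["v0", "v1", "v2"], "p": [1e-8, 1e-5, 1e-3]}
        )
        clumps = clump(assoc, G, r2_threshold=0.1)
        assert {c.index_variant for c in clumps} == {"v0", "v2"}
        lead = next(c for c in clumps if c.index_variant == "v0")
        assert set(lead.members) == {"v0", "v1"}

    def test_single_snp_is_its_own_index(self, rng):
        G = _geno(rng.binomial(2, 0.3, (50, 1)).astype(float))
        clumps = clump(pd.DataFrame({"variant_id": ["v0"], "p": [0.5]}), G)
        assert len(clumps) == 1
        assert clumps[0].index_variant == "v0"
        assert clumps[0].index_p == 0.5

    def test_r2_just_below_threshold_stays_independent(self, rng):
        x, y = _correlated_columns(rng, 2000, 0.3)  # r^2 = 0.09 exactly
        G = _geno(np.column_stack([x, y]))
        assert ld_r2(G, "v0", "v1") == pytest.approx(0.09, abs=1e-9)
        assoc = pd.DataFrame({"variant_id": ["v0", "v1"], "p": [1e-6, 1e-4]})
        assert len(clump(assoc, G, r2_threshold=0.1)) == 2

    def test_missing_reference_variant_rejected(self, rng):
        G = _geno(rng.binomial(2, 0.3, (50, 1)).astype(float))
        with pytest.raises(ValueError, match="missing from LD reference"):
            clump(pd.DataFrame({"variant_id": ["vX"], "p": [0.5]}), G)

    def test_matches_exhaustive_oracle_on_toy_panels(self, rng):
        for _ in range(60):
            m = int(rng.integers(2, 9))
            G = self._random_panel(rng, m)
            pvals = rng.uniform(0, 1, m)
            r2_emp = [
                [ld_r2(G, f"v{i}", f"v{j}") if i != j else 1.0 for j in range(m)]
                for i in range(m)
            ]
            assoc = pd.DataFrame(
                {"variant_id": [f"v{i}" for i in range(m)], "p": pvals}
            )
            got = clump(assoc, G, r2_threshold=0.1)
            expected = _clump_oracle(pvals, r2_emp, 0.1)
            assert [c.index_variant for c in got] == [f"v{i}" for i, _ in expected]
            for c, (_, members) in zip(got, expected):
                assert set(c.members) == {f"v{j}" for j in members}

    def test_partition_and_index_independence(self, rng):
        m = 8
        d = rng.binomial(2, rng.uniform(0.1, 0.4, m), (300, m)).astype(float)
        G = _geno(d)
        assoc = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(m)], "p": rng.uniform(0, 1, m)}
        )
        clumps = clump(assoc, G, r2_threshold=0.1)
        all_members = [v for c in clumps for v in c.members]
        assert sorted(all_members) == sorted(assoc["variant_id"])  # partition
        indices = [c.index_variant for c in clumps]
        for i, a in enumerate(indices):
            for b in indices[i + 1:]:
                assert ld_r2(G, a, b) < 0.1


class TestCumulativeF:
    def test_closed_form(self):
        assert cumulative_f([0.1], 606) == pytest.approx(604 * (0.1 / 0.9), rel=1e-12)
        assert cumulative_f([0.1], 606) == pytest.approx(67.111, abs=0.001)

    def test_zero_r2(self):
        assert cumulative_f([0.0, 0.0], 100) == 0.0

    def test_r2_at_least_one_rejected(self):
        with pytest.raises(ValueError, match="R\\^2 >= 1"):
            cumulative_f([0.6, 0.5], 100)

    def test_weak_instrument_bar(self):
        # R^2 = 0.0165 at n = 606, k = 1 sits just above the F > 10 bar
        assert cumulative_f([0.0165], 606) > 10
        assert cumulative_f([0.016], 606) < 10


class TestScreen:
    def _setup(self, rng, n=500):
        pheno = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.normal(50, 10, n),
                "sex": rng.choice(["female", "male"], n),
                "bmi": rng.normal(27, 5, n),
                "waist": rng.normal(95, 10, n),
                "hip": rng.normal(100, 10, n),
                "smoker": rng.random(n) < 0.1,
            }
        )
        return pheno

    def test_bmi_associated_instrument_excluded_strict_kept_relaxed(self, rng):
        pheno = self._setup(rng)
        bmi_z = (pheno["bmi"] - pheno["bmi"].mean()) / pheno["bmi"].std()
        d = np.clip(1.0 + 0.8 * bmi_z + rng.normal(0, 0.3, len(pheno)), 0, 2)
        G = _geno(d.to_numpy()[:, None])
        G.dosages.index = pheno["sample_id"]
        kept_strict, excl = screen_instruments(G, pheno, ["v0"], mode="strict")
        assert kept_strict == []
        assert excl.iloc[0]["confounder"] == "bmi"
        kept_relaxed, _ = screen_instruments(G, pheno, ["v0"], mode="relaxed")
        assert kept_relaxed == ["v0"]

    def test_null_keep_rate_matches_multiplicity(self, rng):
        # six independent nominal tests: P(keep) ~ 0.95^6 ~ 0.735
        pheno = self._setup(rng, n=400)
        m = 300
        d = rng.binomial(2, 0.3, (400, m)).astype(float)
        G = _geno(d)
        G.dosages.index = pheno["sample_id"]
        kept, _ = screen_instruments(G, pheno, list(G.dosages.columns))
        rate = len(kept) / m
        assert 0.95**6 == pytest.approx(0.735, abs=0.001)
        assert 0.64 < rate < 0.83  # ~4 sigma binomial band around 0.735


def _meth_at(positions, values):
    probes = [f"cg{i}" for i in range(len(positions))]
    ann = pd.DataFrame(
        {"chrom": "1", "pos": positions},
        index=pd.Index(probes, name="probe_id"),
    )
    return MethylationMatrix(values.set_axis(probes, axis=1), ann, scale="m_value")


class TestCisWindow:
    def _data(self, rng, var_positions, probe_positions, n=150):
        m = len(var_positions)
        G = _geno(rng.binomial(2, 0.3, (n, m)).astype(float), positions=var_positions)
        values = pd.DataFrame(
            rng.normal(0, 1, (n, len(probe_positions))), index=G.dosages.index
        )
        M = _meth_at(probe_positions, values)
        pheno = pd.DataFrame(
            {"sample_id": G.dosages.index, "age": rng.normal(50, 10, n),
             "sex": rng.choice(["female", "male"], n)}
        )
        return G, M, pheno

    def test_variant_34bp_away_is_tested(self, rng):
        G, M, pheno = self._data(rng, [1_000_034], [1_000_000])
        table = map_cis_meqtls(G, M, pheno, covariates=("age", "sex"))
        assert len(table) == 1
        assert table.iloc[0]["distance"] == 34

    def test_variant_beyond_1mb_not_tested(self, rng):
        G, M, pheno = self._data(rng, [2_200_000], [1_000_000])
        with pytest.warns(UserWarning, match="no variants"):
            table = map_cis_meqtls(G, M, pheno, covariates=("age", "sex"))
        assert len(table) == 0

    def test_variant_at_probe_coordinate_excluded(self, rng):
        G, M, pheno = self._data(rng, [1_000_000, 1_005_000], [1_000_000])
        table = map_cis_meqtls(G, M, pheno, covariates=("age", "sex"))
        assert set(table["variant_id"]) == {"v1"}

    def test_null_fdp_controlled(self, rng):
        # all-null pairs: the chance of any BH discovery stays near alpha
        n_reps, fdp = 25, []
        for _ in range(n_reps):
            G, M, pheno = self._data(
                rng, list(range(1_000_000, 1_020_000, 1000)),
                [1_005_000, 1_010_000], n=120,
            )
            # 20 variants x 2 probes, minus the two variants sitting exactly
            # on a probe coordinate (overlap exclusion)
            table = map_cis_meqtls(G, M, pheno, covariates=("age", "sex"))
            assert len(table) == 38
            fdp.append(float((table["q"] < 0.05).any()))
        assert np.mean(fdp) <= 0.2
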