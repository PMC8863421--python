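"""QC boundaries, M-value computation and the two correction stages."""

import numpy as np
import pandas as pd
import pytest

from stressmwas import (CohortDesign, QCThresholds, compute_m_values,
                        correct_biological, correct_technical, filter_probes,
                        filter_samples, simulate_methylome, simulate_pedigree)
from stressmwas.preprocess import _batch_variance_share
from stressmwas.synth import MValueMatrix


def _toy_matrix(n_cpgs=6, n_samples=10, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"cg{i}" for i in range(n_cpgs)]
    pos = pd.DataFrame({"chrom": "chr1", "start": np.arange(n_cpgs) * 1000,
                        "end": np.arange(n_cpgs) * 1000 + 1, "cpg_id": ids})
    return MValueMatrix(values=rng.standard_normal((n_cpgs, n_samples)),
                        cpg_ids=ids, positions=pos,
                        sample_ids=[f"S{i}" for i in range(n_samples)])


class TestMValues:
    def test_log_ratio_values(self):
        m = compute_m_values(np.array([[2.0, 4.0, 0.8]]),
                             np.array([[2.0, 1.0, 0.2]]))
        assert m[0] == pytest.approx([0.0, 2.0, 2.0])

    def test_beta_to_m_closed_form(self):
        # beta = 0.8 with unit total intensity is M = log2(0.8/0.2) = 2
        beta = np.array([[0.8]])
        m = compute_m_values(beta, 1 - beta)
        assert m[0, 0] == pytest.approx(np.log2(0.8 / 0.2))

    def test_zero_denominator_guidance(self):
        with pytest.raises(ValueError, match="offset"):
            compute_m_values(np.array([[1.0]]), np.array([[0.0]]))
        out = compute_m_values(np.array([[1.0]]), np.array([[0.0]]), offset=100)
        assert np.isfinite(out).all()

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_m_values(np.array([[-1.0]]), np.array([[1.0]]))


class TestSampleQC:
    def test_detection_fraction_boundary_inclusive(self):
        mat = _toy_matrix(n_cpgs=100, n_samples=4)
        detp = pd.DataFrame(np.zeros((100, 4)))
        detp.iloc[:1, 0] = 0.9    # exactly 1.0% failing sites -> removed
        detp.iloc[0, 1] = 0.9     # 1% too (1/100): removed as well
        out, report = filter_samples(mat, detp)
        assert "S0" in report.removed_samples()
        assert report.n_samples_retained + len(report.removed_samples()) == 4

    def test_below_boundary_retained(self):
        mat = _toy_matrix(n_cpgs=1000, n_samples=3)
        detp = pd.DataFrame(np.zeros((1000, 3)))
        detp.iloc[:9, 0] = 0.9    # 0.9% failing -> retained
        out, report = filter_samples(mat, detp)
        assert report.removed_samples() == set()

    def test_sex_mismatch_removed(self):
        mat = _toy_matrix()
        detp = pd.DataFrame(np.zeros((6, 10)))
        predicted = pd.Series({f"S{i}": "F" for i in range(10)})
        recorded = pd.Series({f"S{i}": "F" for i in range(10)})
        recorded["S3"] = "M"
        out, report = filter_samples(mat, detp, predicted, recorded)
        assert report.samples_removed["sex_mismatch"] == ["S3"]
        assert "S3" not in out.sample_ids

    def test_misaligned_dimensions_rejected(self):
        mat = _toy_matrix()
        with pytest.raises(ValueError, match="detection-P"):
            filter_samples(mat, pd.DataFrame(np.zeros((3, 10))))


class TestProbeQC:
    def test_beadcount_strictly_greater(self):
        mat = _toy_matrix(n_cpgs=3, n_samples=200)
        bead = pd.DataFrame(np.full((3, 200), 10))
        bead.iloc[0, :11] = 2     # 5.5% below 3 -> removed
        bead.iloc[1, :10] = 2     # exactly 5.0% -> retained
        out, report = filter_probes(mat, beadcount=bead)
        assert report.probes_removed["beadcount"] == ["cg0"]
        assert "cg1" in out.cpg_ids

    def test_exclusion_list_applied(self):
        mat = _toy_matrix()
        thr = QCThresholds(exclusion_list=frozenset({"cg2", "cg4"}))
        out, report = filter_probes(mat, thresholds=thr)
        assert set(report.probes_removed["exclusion_list"]) == {"cg2", "cg4"}
        assert len(out.cpg_ids) == 4

    def test_rule_order_insensitive(self):
        mat = _toy_matrix(n_cpgs=50, n_samples=100, seed=3)
        rng = np.random.default_rng(5)
        bead = pd.DataFrame(rng.integers(2, 10, (50, 100)))
        detp = pd.DataFrame(rng.random((50, 100)) * 0.1)
        both, _ = filter_probes(mat, beadcount=bead, detection_p=detp)
        a, _ = filter_probes(mat, beadcount=bead)
        ab, _ = filter_probes(a, detection_p=detp.iloc[
            [int(c[2:]) for c in a.cpg_ids]].reset_index(drop=True))
        b, _ = filter_probes(mat, detection_p=detp)
        ba, _ = filter_probes(b, beadcount=bead.iloc[
            [int(c[2:]) for c in b.cpg_ids]].reset_index(drop=True))
        assert ab.cpg_ids == ba.cpg_ids == both.cpg_ids

    def test_clean_input_is_noop(self):
        mat = _toy_matrix()
        bead = pd.DataFrame(np.full((6, 10), 10))
        detp = pd.DataFrame(np.zeros((6, 10)))
        out, report = filter_probes(mat, beadcount=bead, detection_p=detp)
        assert out.cpg_ids == mat.cpg_ids
        out2, report2 = filter_samples(mat, detp)
        assert out2.sample_ids == mat.sample_ids


class TestTechnicalCorrection:
    def _cohort(self, plate_frac, seed=10, n=150, p=60):
        design = CohortDesign(
            n_individuals=n, n_cpgs=p, seed=seed, plate_size=25,
            variance_fractions={"plate": plate_frac,
                                "residual": 1.0 - plate_frac})
        rel = simulate_pedigree(design)
        mat, _ = simulate_methylome(design, rel)
        batch = rel.samples[["plate", "draw_date", "position", "set_id"]]
        return mat, batch, rel

    def test_zero_batch_variance_matches_ols(self):
        # exact limit: frozen zero batch variances reproduce OLS residuals;
        # estimated variances approach them (chance batch variance is small
        # but nonzero in finite samples)
        mat, batch, _ = self._cohort(plate_frac=0.0)
        from stressmwas.preprocess import _design_from_covariates
        from stressmwas.reml import fit_airelm_lowrank
        X = _design_from_covariates(batch.drop(columns=["plate", "draw_date"]))
        n = len(mat.sample_ids)
        factors = []
        for col in ("plate", "draw_date"):
            codes, levels = pd.factorize(batch[col])
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), codes] = 1.0
            factors.append(Z)
        y = mat.values[0]
        q, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_resid = y - X @ q
        frozen = fit_airelm_lowrank(y, X, factors, max_iter=0,
                                    init=np.array([1e-12, 1e-12, y.var()]))
        assert frozen.resid == pytest.approx(ols_resid, abs=1e-6)
        corrected = correct_technical(mat, batch)
        for j in range(0, 60, 7):
            qj, *_ = np.linalg.lstsq(X, mat.values[j], rcond=None)
            r = np.corrcoef(corrected.values[j], mat.values[j] - X @ qj)[0, 1]
            assert r > 0.98

    def test_plate_share_removed(self):
        mat, batch, rel = self._cohort(plate_frac=0.4, p=100)
        corrected = correct_technical(mat, batch)
        share = _batch_variance_share(corrected.values,
                                      rel.samples["plate"].to_numpy())
        assert share < 0.02

    def test_residuals_orthogonal_to_fixed_design(self):
        mat, batch, _ = self._cohort(plate_frac=0.3)
        corrected = correct_technical(mat, batch)
        from stressmwas.preprocess import _design_from_covariates
        X = _design_from_covariates(batch.drop(columns=["plate", "draw_date"]))
        for j in range(0, 60, 11):
            r = corrected.values[j]
            corrs = X.T @ r
            assert np.abs(corrs).max() < 1e-8

    def test_dimensions_and_centering_preserved(self):
        mat, batch, _ = self._cohort(plate_frac=0.2)
        corrected = correct_technical(mat, batch)
        assert corrected.values.shape == mat.values.shape
        assert np.abs(corrected.values.mean(axis=1)).max() < 1e-8
        assert corrected.provenance == "technical"


class TestBiologicalCorrection:
    def _fit(self, frac_k, seed=11, n=200, p=80):
        design = CohortDesign(
            n_individuals=n, n_cpgs=p, seed=seed,
            variance_fractions={"K": frac_k, "residual": 1.0 - frac_k})
        rel = simulate_pedigree(design)
        mat, _ = simulate_methylome(design, rel)
        cells = mat.sample_meta[["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]]
        return design, rel, mat, cells

    def test_identity_matrices_collapse_to_ols(self):
        design, rel, mat, cells = self._fit(frac_k=0.0, p=30)
        n = len(mat.sample_ids)
        eye = {lab: np.eye(n) for lab in ["G", "K", "F", "C", "S"]}
        corrected, vc = correct_biological(mat, eye, rel.samples["sex"],
                                           rel.samples["age"], cells)
        from stressmwas.preprocess import _design_from_covariates
        fixed = pd.concat([pd.DataFrame({"sex": rel.samples["sex"].to_numpy(),
                                         "age": rel.samples["age"].to_numpy()}),
                           cells.reset_index(drop=True)], axis=1)
        X = _design_from_covariates(fixed)
        # with all matrices equal to the identity, flat variance is resolved
        # into the residual, so the model collapses exactly to OLS
        for j in range(0, 30, 5):
            q, *_ = np.linalg.lstsq(X, mat.values[j], rcond=None)
            assert corrected.values[j] == pytest.approx(mat.values[j] - X @ q,
                                                        abs=1e-6)

    def test_sibling_correlation_removed(self):
        design, rel, mat, cells = self._fit(frac_k=0.35, n=300, p=150)
        corrected, _ = correct_biological(mat, rel.matrices,
                                          rel.samples["sex"],
                                          rel.samples["age"], cells)
        K = rel.matrices["K"]
        iu = np.triu_indices_from(K, k=1)
        pairs = [(a, b) for a, b in zip(*iu) if K[a, b] >= 0.5]

        def pooled_r(vals):
            v = vals - vals.mean(axis=1, keepdims=True)
            a = np.array([v[:, i] for i, _ in pairs]).ravel()
            b = np.array([v[:, j] for _, j in pairs]).ravel()
            return np.corrcoef(a, b)[0, 1]

        raw_r = pooled_r(mat.values)
        cor_r = pooled_r(corrected.values)
        assert raw_r > 0.12                 # positive familial structure before
        # the mixed-model (BLUP) residual removes the positive familial
        # correlation; what remains is the small negative off-diagonal of
        # V^-1 that whitening theory predicts
        Vt = 0.35 * K + 0.65 * np.eye(K.shape[0])
        Vi = np.linalg.inv(Vt)
        theory = (np.mean([Vi[a, b] for a, b in pairs]) /
                  np.mean([np.sqrt(Vi[a, a] * Vi[b, b]) for a, b in pairs]))
        assert cor_r < 0.02                 # no positive correlation remains
        assert cor_r == pytest.approx(theory, abs=0.06)

    def test_variance_fractions_recovered(self):
        # identifiable subset {K, F, S}: C is a linear combination of the
        # others on purely nuclear pedigrees, so it is generated at zero and
        # left out of the fit
        design = CohortDesign(
            n_individuals=350, n_cpgs=120, seed=12,
            variance_fractions={"K": 0.3, "F": 0.15, "S": 0.1,
                                "residual": 0.45})
        rel = simulate_pedigree(design)
        mat, _ = simulate_methylome(design, rel)
        cells = mat.sample_meta[["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]]
        sub = {lab: rel.matrices[lab] for lab in ["K", "F", "S"]}
        corrected, vc = correct_biological(mat, sub, rel.samples["sex"],
                                           rel.samples["age"], cells)
        means = vc[["K", "F", "S", "residual"]].mean()
        assert means["K"] == pytest.approx(0.30, abs=0.1)
        assert means["F"] == pytest.approx(0.15, abs=0.1)
        assert means["S"] == pytest.approx(0.10, abs=0.1)
        assert means["residual"] == pytest.approx(0.45, abs=0.1)

    def test_non_psd_matrix_rejected(self):
        design, rel, mat, cells = self._fit(frac_k=0.2, n=60, p=5)
        bad = dict(rel.matrices)
        m = np.eye(60)
        m[0, 1] = m[1, 0] = 2.0
        bad["K"] = m
        with pytest.raises(ValueError, match="PSD"):
            correct_biological(mat, bad, rel.samples["sex"],
                               rel.samples["age"], cells)
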