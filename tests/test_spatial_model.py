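"""P-spline mixed model: bases, REML fit, heritability, corrected values."""

import numpy as np
import pandas as pd
import pytest

from thermofield import spatial_model as sm
from thermofield import trial_design as td
from thermofield.errors import EstimabilityError, InputError, ModeError, ParameterError


def simulate_grid_data(design, var_g=0.6, var_p=0.8, var_row=0.0, surface=None,
                       seed=0, baseline=0.0):
    """Response on a design's virtual grid with known variance components."""
    rng = np.random.default_rng(seed)
    genos = sorted({p.genotype_id for p in design.plots if not p.is_filler})
    g_eff = dict(zip(genos, np.sqrt(var_g) * rng.standard_normal(len(genos))))
    nrow = max(p.virtual_row for p in design.plots)
    r_eff = np.sqrt(var_row) * rng.standard_normal(nrow)
    rows = []
    for p in design.plots:
        if p.is_filler:
            continue
        y = baseline + g_eff[p.genotype_id] + r_eff[p.virtual_row - 1]
        y += np.sqrt(var_p) * rng.standard_normal()
        if surface is not None:
            y += surface(p.virtual_row, p.virtual_range)
        rows.append((p.plot_id, y, p.virtual_row, p.virtual_range, p.genotype_id))
    return pd.DataFrame(rows, columns=["plot_id", "y", "virtual_row",
                                       "virtual_range", "genotype_id"])


@pytest.fixture(scope="module")
def grid_756(full_design):
    return simulate_grid_data(full_design, seed=42)


class TestBuildBases:
    def test_two_thirds_knot_counts(self):
        basis = sm.build_bases(74, 18)
        assert basis.knot_counts == (49, 12)

    def test_partition_of_unity(self):
        basis = sm.build_bases(30, 10)
        x = np.linspace(1, 30, 77)
        B = basis.row.bspline(x)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_penalty_null_space_dimension_two(self):
        basis = sm.build_bases(30, 10)
        m = basis.row.n_knots + 3
        d2 = np.diff(np.eye(m), n=2, axis=0)
        evals = np.linalg.eigvalsh(d2.T @ d2)
        assert (evals < 1e-10).sum() == 2
        assert len(basis.row.eigvals) == m - 2

    def test_too_few_knots_rejected(self):
        with pytest.raises(ParameterError):
            sm.build_bases(5, 18, fraction=0.5)
        with pytest.raises(ParameterError):
            sm.build_bases(3, 18)

    def test_round_half_up(self):
        assert sm.round_half_up(49.33) == 49
        assert sm.round_half_up(49.5) == 50
        assert sm.round_half_up(12.0) == 12


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["random", "fixed"])
    @pytest.mark.parametrize("shape", [(8, 6), (6, 8), (6, 6)])
    def test_henderson_equals_dense_gls(self, mode, shape):
        """For fixed variance components on a <= 48-cell grid, the mixed-model
        solve must equal a dense GLS solve of the same model to 1e-8."""
        nr, nc = shape
        rng = np.random.default_rng(nr * 100 + nc)
        cells = [(r, c) for r in range(1, nr + 1) for c in range(1, nc + 1)]
        geno = rng.integers(0, 12, len(cells))
        df = pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(len(cells))],
            "y": rng.normal(size=len(cells)) + 0.4 * geno,
            "virtual_row": [r for r, _ in cells],
            "virtual_range": [c for _, c in cells],
            "genotype_id": [f"G{g:02d}" for g in geno],
        })
        basis = sm.build_bases(nr, nc)
        X, z_blocks, _, _, _ = sm._design_matrices(df, basis, mode)
        sizes = [z.shape[1] for _, z in z_blocks]
        Z = np.hstack([z for _, z in z_blocks])
        y = df["y"].to_numpy()
        rng2 = np.random.default_rng(1)
        sig2 = 0.8
        sig2_k = rng2.uniform(0.2, 2.0, len(sizes))

        # Henderson mixed-model equations (implementation path)
        p = X.shape[1]
        off = np.concatenate([[0], np.cumsum(sizes)])
        M = np.hstack([X, Z])
        C = M.T @ M
        for k, s in enumerate(sizes):
            sl = slice(p + off[k], p + off[k + 1])
            C[sl, sl] += np.eye(s) * (sig2 / sig2_k[k])
        coef = np.linalg.solve(C, M.T @ y)

        # dense GLS oracle: V = sig2 I + Z G Z'
        G = np.concatenate([np.full(s, v) for s, v in zip(sizes, sig2_k)])
        V = sig2 * np.eye(len(y)) + (Z * G) @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = G * (Z.T @ (Vi @ (y - X @ beta)))
        assert np.allclose(coef[:p], beta, atol=1e-8)
        assert np.allclose(coef[p:], u, atol=1e-8)


class TestFitSpats:
    def test_zero_variance_response_collapses(self, full_design):
        df = simulate_grid_data(full_design, var_g=0, var_p=0, seed=0, baseline=5.0)
        fit = sm.fit_spats(df, "random", grid_shape=(74, 18))
        assert fit.intercept == pytest.approx(5.0)
        assert all(v == 0.0 for v in fit.var_components.values())
        assert sm.heritability(fit).h2 == 0.0

    def test_residuals_plus_fitted_reconstruct_response(self, grid_756):
        fit = sm.fit_spats(grid_756, "random", grid_shape=(74, 18))
        assert np.allclose(fit.fitted + fit.residuals, grid_756["y"], atol=1e-10)

    def test_ed_accounting_sums_to_n(self, grid_756):
        fit = sm.fit_spats(grid_756, "random", grid_shape=(74, 18))
        total = sum(v for k, v in fit.eds.items() if k != "fixed")
        total += fit.eds["fixed"] + fit.ed_residual
        assert total == pytest.approx(len(grid_756), abs=1e-6)

    def test_ed_genotype_within_bounds(self, grid_756):
        fit = sm.fit_spats(grid_756, "random", grid_shape=(74, 18))
        assert 0.0 <= fit.eds["genotype"] <= 354 - 1

    def test_h2_monotone_in_genotypic_variance(self):
        """Mean estimated H^2 must increase strictly with the simulated
        genotypic variance (sigma_g^2 in {0.25, 1, 4}, sigma^2 = 1)."""
        design = td.generate_design(n_test=81, check_ids=("A", "B", "C"),
                                    rep_shape=(15, 6), check_block_shape=(5, 6),
                                    seed=3)
        td.build_virtual_grid(design, (1, 15), (20, 34))
        means = []
        for var_g in (0.25, 1.0, 4.0):
            h2s = []
            for rep in range(20):
                df = simulate_grid_data(design, var_g=var_g, var_p=1.0,
                                        seed=1000 + rep)
                fit = sm.fit_spats(df, "random", grid_shape=(34, 6))
                h2s.append(sm.heritability(fit).h2)
            means.append(np.mean(h2s))
        assert means[0] < means[1] < means[2]

    def test_blue_blup_correlation(self, grid_756):
        fr = sm.fit_spats(grid_756, "random", grid_shape=(74, 18))
        ff = sm.fit_spats(grid_756, "fixed", grid_shape=(74, 18))
        blup = sm.genotype_predictions(fr)
        blue = sm.genotype_predictions(ff)
        r = np.corrcoef(blue.to_numpy(), blup[blue.index].to_numpy())[0, 1]
        assert r > 0.99

    def test_confounded_genotype_raises(self):
        # every genotype sits in exactly one row: dummies alias the row axis
        rows = []
        for r in range(1, 5):
            for c in range(1, 5):
                rows.append((f"p{r}{c}", float(r), r, c, f"G{r}"))
        df = pd.DataFrame(rows, columns=["plot_id", "y", "virtual_row",
                                         "virtual_range", "genotype_id"])
        with pytest.raises(EstimabilityError):
            sm.fit_spats(df, "fixed", fraction=1.0, grid_shape=(4, 4))

    def test_constant_genotype_rejected(self):
        df = pd.DataFrame({"plot_id": list("abcd"), "y": [1.0, 2, 3, 4],
                           "virtual_row": [1, 1, 2, 2], "virtual_range": [1, 2, 1, 2],
                           "genotype_id": "G1"})
        with pytest.raises(InputError):
            sm.fit_spats(df, "random")

    def test_nonconvergence_flagged(self, grid_756):
        fit = sm.fit_spats(grid_756, "random", grid_shape=(74, 18), max_iter=2)
        assert not fit.converged
        assert fit.n_iter == 2
        assert len(fit.deviance) == 2


class TestHeritability:
    @pytest.mark.parametrize("ed,n,want", [(0.0, 100, 0.0), (99.0, 100, 1.0),
                                           (176.5, 354, 0.5)])
    def test_formula(self, ed, n, want):
        fit = _stub_fit(ed, n)
        assert sm.heritability(fit).h2 == pytest.approx(want)

    def test_fixed_mode_rejected(self, grid_756):
        ff = sm.fit_spats(grid_756, "fixed", grid_shape=(74, 18))
        with pytest.raises(ModeError):
            sm.heritability(ff)


def _stub_fit(ed_g, n_g):
    return sm.SpatialFit(
        mode="random", data=pd.DataFrame(), basis=None, intercept=0.0,
        genotype_effects=pd.Series(dtype=float), row_effects=pd.Series(dtype=float),
        surface=np.zeros(1), fitted=np.zeros(1), residuals=np.zeros(1),
        var_components={"genotype": 1.0, "residual": 1.0},
        eds={"genotype": ed_g}, ed_residual=0.0, deviance=[], converged=True,
        n_iter=1, genotype_levels=[f"G{i}" for i in range(n_g)],
    )


class TestCorrectedValues:
    def test_mean_identity(self, grid_756):
        ff = sm.fit_spats(grid_756, "fixed", grid_shape=(74, 18))
        cv = sm.corrected_values(ff)
        blues = grid_756["genotype_id"].map(ff.genotype_effects).to_numpy()
        want = ff.intercept + blues.mean() + ff.residuals.mean()
        assert cv["corrected"].mean() == pytest.approx(want, abs=1e-10)

    def test_corrected_reconstructs_without_surface_and_rows(self, grid_756):
        ff = sm.fit_spats(grid_756, "fixed", grid_shape=(74, 18))
        cv = sm.corrected_values(ff)
        rowfx = grid_756["virtual_row"].map(ff.row_effects).to_numpy()
        recon = cv["corrected"].to_numpy() + ff.surface + rowfx
        assert np.allclose(recon, grid_756["y"], atol=1e-8)

    def test_injected_surface_absorbed(self, full_design):
        """Adding a smooth surface orthogonal to the unpenalized trend space
        leaves the corrected values essentially unchanged."""
        base_surface = lambda r, c: (1.0 * np.sin(2 * np.pi * r / 74 + 0.7)
                                     + 0.8 * np.cos(2 * np.pi * c / 18 + 0.3))
        df = simulate_grid_data(full_design, var_g=0.6, var_p=0.25, seed=5,
                                surface=base_surface)
        fit1 = sm.fit_spats(df, "fixed", grid_shape=(74, 18))
        cv1 = sm.corrected_values(fit1)

        vr = df["virtual_row"].to_numpy(dtype=float)
        vc = df["virtual_range"].to_numpy(dtype=float)
        basis = sm.build_bases(74, 18)
        Xn = np.column_stack([np.ones(len(df)), basis.fixed_part(vr, vc)])
        add = 0.5 * (np.sin(2 * np.pi * vr / 74) - 0.6 * np.cos(2 * np.pi * vc / 18))
        add = add - Xn @ np.linalg.lstsq(Xn, add, rcond=None)[0]
        df2 = df.copy()
        df2["y"] = df2["y"] + add
        fit2 = sm.fit_spats(df2, "fixed", grid_shape=(74, 18))
        cv2 = sm.corrected_values(fit2)
        diff = cv2["corrected"].to_numpy() - cv1["corrected"].to_numpy()
        assert np.abs(diff).max() <= 0.05

    def test_random_mode_rejected(self, grid_756):
        fr = sm.fit_spats(grid_756, "random", grid_shape=(74, 18))
        with pytest.raises(ModeError):
            sm.corrected_values(fr)

    def test_surface_grid_covers_gap(self, grid_756):
        fit = sm.fit_spats(grid_756, "random", grid_shape=(74, 18))
        sg = sm.surface_grid(fit)
        assert len(sg) == 74 * 18
        assert np.isfinite(sg["surface"]).all()
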