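"""P-spline spatial mixed model for field-trial correction and heritability.

The plot response (canopy temperature, usually as ``delta_t``) observed on a
virtual row x range grid is modelled as

    Y = f(r, c) + Z_g c_g + Z_r c_r + eps

where ``f`` is a smooth bivariate surface, ``c_g`` are genotype effects
(random, or fixed when BLUEs are wanted), ``c_r ~ N(0, sigma_r^2 I)`` are
random row effects capturing the strong working-direction pattern, and
``eps ~ N(0, sigma^2 I)``.

The surface uses the PS-ANOVA construction: cubic B-spline bases along rows
and ranges with second-order difference penalties are reparameterized
spectrally so the unpenalized null space (intercept, linear trends and their
product) moves to the fixed part and five smooth random components remain -
the two smooth main effects f(r) and f(c), the two linear-by-smooth
interactions f(r):c and r:f(c), and the smooth-by-smooth interaction
f(r):f(c) - each with its own smoothing variance (the interaction carries a
single variance after rescaling by its Kronecker-sum penalty eigenvalues).

Restricted maximum likelihood uses the effective-dimension fixed point
(Schall/SAP iteration): given variances, the Henderson mixed-model equations
are solved; each variance is updated as ``u_k'u_k / ED_k`` with ``ED_k =
q_k - (sigma^2 / sigma_k^2) tr(C^-1_kk)``, and the residual variance as
``RSS / (n - rank(X) - sum ED_k)``, until the relative change of the REML
deviance falls below the tolerance.

The generalized heritability is ``H^2 = ED_g / (n_g - 1)``: the effective
dimension absorbed by the genotype term relative to its upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.linalg import LinAlgError, cho_solve, cholesky, solve_triangular

from .errors import (
    EstimabilityError,
    FitError,
    InputError,
    ModeError,
    ParameterError,
)

DEFAULT_SPLINE_FRACTION = 2.0 / 3.0

SMOOTH_TERMS = ("f(r)", "f(c)", "f(r):c", "r:f(c)", "f(r):f(c)")


def round_half_up(x: float) -> int:
    """Knot-count rounding: 0.5 always rounds up (74 * 2/3 -> 49)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# basis construction


@dataclass
class AxisBasis:
    """Spectrally reparameterized cubic P-spline basis for one grid axis."""

    n: int  # grid extent (number of rows or ranges)
    n_knots: int  # spline segments along the axis
    knots: np.ndarray  # full (extended) knot vector
    u_null: np.ndarray  # basis-space null vectors of the penalty (dim 2)
    u_pos: np.ndarray  # penalized eigenvectors
    eigvals: np.ndarray  # positive penalty eigenvalues, ascending

    def bspline(self, x: np.ndarray) -> np.ndarray:
        """Raw cubic B-spline design matrix at positions ``x``."""
        return interpolate.BSpline.design_matrix(
            np.asarray(x, dtype=float), self.knots, 3
        ).toarray()

    def z(self, x: np.ndarray) -> np.ndarray:
        """Transformed smooth part: identity penalty, iid random effects."""
        return self.bspline(x) @ self.u_pos / np.sqrt(self.eigvals)

    def z_unscaled(self, x: np.ndarray) -> np.ndarray:
        return self.bspline(x) @ self.u_pos

    def linear(self, x: np.ndarray) -> np.ndarray:
        """Centered, scaled linear covariate (the penalty null space minus
        the intercept)."""
        x = np.asarray(x, dtype=float)
        return (x - (self.n + 1) / 2.0) / (self.n / 2.0)


def _axis_basis(n: int, fraction: float) -> AxisBasis:
    if n < 4:
        raise ParameterError(f"grid axis of {n} cells is too short (need >= 4)")
    nseg = round_half_up(fraction * n)
    if nseg < 4:
        raise ParameterError(
            f"spline-point fraction {fraction} yields only {nseg} knots on a "
            f"{n}-cell axis (need >= 4)"
        )
    lo, hi = 1.0, float(n)
    h = (hi - lo) / nseg
    knots = lo + h * np.arange(-3, nseg + 4)
    m = nseg + 3  # number of cubic B-spline coefficients
    d2 = np.diff(np.eye(m), n=2, axis=0)
    evals, evecs = np.linalg.eigh(d2.T @ d2)
    # second-order penalty: 2-dimensional null space (constant + linear)
    return AxisBasis(
        n=n,
        n_knots=nseg,
        knots=knots,
        u_null=evecs[:, :2],
        u_pos=evecs[:, 2:],
        eigvals=np.maximum(evals[2:], 0.0),
    )


@dataclass
class PSAnovaBasis:
    """Tensor-product PS-ANOVA decomposition over the virtual grid."""

    row: AxisBasis
    col: AxisBasis

    @property
    def knot_counts(self) -> tuple[int, int]:
        return (self.row.n_knots, self.col.n_knots)

    def fixed_part(self, r: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Unpenalized surface columns: linear trends and their product."""
        rt, ct = self.row.linear(r), self.col.linear(c)
        return np.column_stack([rt, ct, rt * ct])

    def smooth_parts(self, r: np.ndarray, c: np.ndarray) -> dict[str, np.ndarray]:
        """The five iid smooth random components evaluated at (r, c)."""
        rt, ct = self.row.linear(r), self.col.linear(c)
        zr, zc = self.row.z(r), self.col.z(c)
        zru, zcu = self.row.z_unscaled(r), self.col.z_unscaled(c)
        # smooth x smooth: Kronecker-sum penalty eigenvalues -> identity
        lam = (self.row.eigvals[:, None] + self.col.eigvals[None, :]).ravel()
        inter = (zru[:, :, None] * zcu[:, None, :]).reshape(len(zru), -1) / np.sqrt(lam)
        return {
            "f(r)": zr,
            "f(c)": zc,
            "f(r):c": zr * ct[:, None],
            "r:f(c)": zc * rt[:, None],
            "f(r):f(c)": inter,
        }


def build_bases(
    n_rows: int, n_ranges: int, fraction: float = DEFAULT_SPLINE_FRACTION
) -> PSAnovaBasis:
    """Row/range cubic B-spline bases with second-order difference penalties
    and the PS-ANOVA tensor decomposition.

    Knot (segment) counts are ``round(fraction * n)`` per axis with
    half-up rounding.
    """
    return PSAnovaBasis(row=_axis_basis(n_rows, fraction), col=_axis_basis(n_ranges, fraction))


# ---------------------------------------------------------------------------
# data container


def make_grid_data(
    ct: pd.DataFrame,
    design_frame: pd.DataFrame,
    response: str = "delta_t",
) -> pd.DataFrame:
    """Join a plot-CT table with the design table into model input.

    Returns columns ``plot_id, y, virtual_row, virtual_range, genotype_id``;
    plots with missing response are dropped (complete-case) and duplicated
    grid cells rejected.
    """
    df = ct.merge(
        design_frame[["plot_id", "genotype_id", "virtual_row", "virtual_range"]],
        on="plot_id",
        how="inner",
    )
    df = df.rename(columns={response: "y"})[
        ["plot_id", "y", "virtual_row", "virtual_range", "genotype_id"]
    ]
    df = df[df["y"].notna() & df["genotype_id"].notna()].reset_index(drop=True)
    if df.duplicated(["virtual_row", "virtual_range"]).any():
        raise InputError("duplicated virtual grid cells in model input")
    return df


# ---------------------------------------------------------------------------
# the fit


@dataclass
class SpatialFit:
    """Fitted spatial mixed model."""

    mode: str  # "random" or "fixed" genotypes
    data: pd.DataFrame  # model input (one row per used plot)
    basis: PSAnovaBasis
    intercept: float
    genotype_effects: pd.Series  # BLUPs (random) or BLUEs (fixed, ref = 0)
    row_effects: pd.Series
    surface: np.ndarray  # fitted f(r, c) per observation (trend + smooths)
    fitted: np.ndarray
    residuals: np.ndarray
    var_components: dict[str, float]  # sigma_k^2 per term + "residual"
    eds: dict[str, float]  # effective dimension per term
    ed_residual: float
    deviance: list[float]
    converged: bool
    n_iter: int
    genotype_levels: list[str] = dc_field(default_factory=list)
    smooth_centers: dict = dc_field(default_factory=dict)
    trend_coefs: np.ndarray | None = None  # linear-trend surface coefficients
    smooth_coefs: dict = dc_field(default_factory=dict)  # per smooth term

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_levels)

    @property
    def ed_genotype(self) -> float:
        if self.mode != "random":
            raise ModeError("ED_g is defined for genotypes-random fits")
        return self.eds["genotype"]

    def summary_frame(self) -> pd.DataFrame:
        rows = [(k, self.var_components.get(k, np.nan), self.eds.get(k, np.nan))
                for k in self.eds]
        rows.append(("residual", self.var_components["residual"], self.ed_residual))
        return pd.DataFrame(rows, columns=["term", "variance", "effective_dimension"])


def _design_matrices(data: pd.DataFrame, basis: PSAnovaBasis, mode: str):
    r = data["virtual_row"].to_numpy(dtype=float)
    c = data["virtual_range"].to_numpy(dtype=float)
    n = len(data)
    geno = pd.Categorical(data["genotype_id"])
    glevels = list(geno.categories)
    g_ind = np.zeros((n, len(glevels)))
    g_ind[np.arange(n), geno.codes] = 1.0
    rows = pd.Categorical(data["virtual_row"])
    rlevels = list(rows.categories)
    r_ind = np.zeros((n, len(rlevels)))
    r_ind[np.arange(n), rows.codes] = 1.0

    X = [np.ones((n, 1)), basis.fixed_part(r, c)]
    if mode == "fixed":
        X.append(g_ind[:, 1:])  # treatment coding, first level = reference
    X = np.hstack(X)

    # smooth components are centered over the observed cells (sum-to-zero
    # identifiability constraint) so constants cannot migrate between the
    # intercept and the surface
    centers = {}
    z_blocks = []
    for nm, zb in basis.smooth_parts(r, c).items():
        centers[nm] = zb.mean(axis=0)
        z_blocks.append((nm, zb - centers[nm]))
    if mode == "random":
        z_blocks.append(("genotype", g_ind))
    z_blocks.append(("row", r_ind))
    return X, z_blocks, glevels, rlevels, centers


def fit_spats(
    data: pd.DataFrame,
    genotype_mode: str = "random",
    fraction: float = DEFAULT_SPLINE_FRACTION,
    grid_shape: tuple[int, int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> SpatialFit:
    """Fit the spatial model by ED-based REML.

    ``data`` comes from :func:`make_grid_data`.  ``grid_shape`` is the full
    virtual grid (rows, ranges) the spline bases span - by default the
    maximum observed coordinates - so the surface bridges unobserved gap
    rows smoothly.  In ``fixed`` mode genotypes enter the fixed part
    (treatment coding; the reported effects are BLUEs with the first level
    as reference).
    """
    if genotype_mode not in ("random", "fixed"):
        raise ParameterError(f"unknown genotype_mode {genotype_mode!r}")
    y = data["y"].to_numpy(dtype=float)
    n = len(y)
    if n < 4:
        raise InputError("need at least 4 observations")
    if data["genotype_id"].nunique() < 2:
        raise InputError("genotype factor is constant")
    for axis in ("virtual_row", "virtual_range"):
        if data[axis].nunique() < 2:
            raise InputError(f"need >= 2 distinct {axis} positions")
    if grid_shape is None:
        grid_shape = (int(data["virtual_row"].max()), int(data["virtual_range"].max()))
    basis = build_bases(grid_shape[0], grid_shape[1], fraction)
    X, z_blocks, glevels, rlevels, centers = _design_matrices(data, basis, genotype_mode)
    p = X.shape[1]
    names = [nm for nm, _ in z_blocks]
    sizes = [zb.shape[1] for _, zb in z_blocks]
    Z = np.hstack([zb for _, zb in z_blocks])
    q = Z.shape[1]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    var_y = float(np.var(y))
    if var_y <= 1e-300:
        # degenerate flat response: everything collapses to zero
        zero_eds = {nm: 0.0 for nm in names}
        return SpatialFit(
            mode=genotype_mode, data=data, basis=basis, intercept=float(y.mean()),
            genotype_effects=pd.Series(0.0, index=glevels),
            row_effects=pd.Series(0.0, index=rlevels),
            surface=np.zeros(n), fitted=np.full(n, y.mean()),
            residuals=y - y.mean(),
            var_components={**{nm: 0.0 for nm in names}, "residual": 0.0},
            eds=zero_eds, ed_residual=float(n - 1), deviance=[], converged=True,
            n_iter=0, genotype_levels=glevels,
        )

    M = np.hstack([X, Z])
    MtM = M.T @ M
    Mty = M.T @ y
    yty = float(y @ y)

    sig2 = var_y / 10.0
    sig2_k = np.full(len(z_blocks), var_y / 10.0)
    dev_trace: list[float] = []
    converged = False
    it = 0
    beta = coef = None
    eds = np.zeros(len(z_blocks))
    for it in range(1, max_iter + 1):
        C = MtM.copy()
        for k in range(len(z_blocks)):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            C[sl, sl] += np.eye(sizes[k]) * (sig2 / sig2_k[k])
        try:
            L = cholesky(C, lower=True)
        except LinAlgError as exc:
            raise EstimabilityError(
                "singular mixed-model equations (genotype confounded with the "
                "design?)"
            ) from exc
        coef = cho_solve((L, True), Mty)
        beta, u = coef[:p], coef[p:]
        rss = yty - float(coef @ Mty)  # y'y - coef'M'y = e'e + shrinkage term
        # effective dimensions from block traces of C^-1
        Linv = solve_triangular(L, np.eye(L.shape[0]), lower=True)
        colsq = np.sum(Linv**2, axis=0)
        for k in range(len(z_blocks)):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            eds[k] = sizes[k] - (sig2 / sig2_k[k]) * float(np.sum(colsq[sl]))
        eds = np.clip(eds, 1e-10, None)
        ed_res = n - p - float(np.sum(eds))
        # REML deviance (constants dropped)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
        dev = (
            (n - p - q) * math.log(sig2)
            + float(np.dot(sizes, np.log(sig2_k)))
            + logdetC
            + rss / sig2
        )
        dev_trace.append(dev)
        # fixed-point updates
        new_k = sig2_k.copy()
        for k in range(len(z_blocks)):
            uk = u[offsets[k] : offsets[k + 1]]
            new_k[k] = max(float(uk @ uk) / eds[k], 1e-12 * var_y)
        e = y - M @ coef
        new_sig2 = max(float(e @ e) / max(ed_res, 1.0), 1e-12 * var_y)
        if len(dev_trace) > 1 and abs(dev_trace[-1] - dev_trace[-2]) < tol * (
            abs(dev_trace[-2]) + 0.1
        ):
            converged = True
            break
        sig2_k, sig2 = new_k, new_sig2

    u = coef[p:]
    fitted = M @ coef
    resid = y - fitted
    # surface = linear trends + the five smooth components
    surf = X[:, 1:4] @ beta[1:4]
    for k, nm in enumerate(names):
        if nm in SMOOTH_TERMS:
            sl = slice(offsets[k], offsets[k + 1])
            surf = surf + Z[:, sl] @ u[sl]

    u_smooth = {nm: u[offsets[k] : offsets[k + 1]]
                for k, nm in enumerate(names) if nm in SMOOTH_TERMS}
    var_components = {nm: float(sig2_k[k]) for k, nm in enumerate(names)}
    var_components["residual"] = float(sig2)
    ed_map = {nm: float(eds[k]) for k, nm in enumerate(names)}
    ed_map["fixed"] = float(p)

    if genotype_mode == "random":
        k_g = names.index("genotype")
        g_eff = pd.Series(u[offsets[k_g] : offsets[k_g + 1]], index=glevels)
    else:
        g_eff = pd.Series(np.concatenate([[0.0], beta[4:]]), index=glevels)
    k_r = names.index("row")
    r_eff = pd.Series(u[offsets[k_r] : offsets[k_r + 1]], index=rlevels)

    return SpatialFit(
        mode=genotype_mode,
        data=data,
        basis=basis,
        intercept=float(beta[0]),
        genotype_effects=g_eff,
        row_effects=r_eff,
        surface=np.asarray(surf),
        fitted=np.asarray(fitted),
        residuals=np.asarray(resid),
        var_components=var_components,
        eds=ed_map,
        ed_residual=float(n - p - float(np.sum(eds))),
        deviance=dev_trace,
        converged=converged,
        n_iter=it,
        genotype_levels=glevels,
        smooth_centers=centers,
        trend_coefs=np.asarray(beta[1:4]),
        smooth_coefs=u_smooth,
    )


def surface_grid(fit: SpatialFit) -> pd.DataFrame:
    """Fitted surface evaluated on every cell of the full virtual grid
    (including the unobserved gap rows), for visualization/export."""
    basis = fit.basis
    nr, nc = basis.row.n, basis.col.n
    rr, cc = np.meshgrid(np.arange(1, nr + 1, dtype=float),
                         np.arange(1, nc + 1, dtype=float), indexing="ij")
    r, c = rr.ravel(), cc.ravel()
    vals = basis.fixed_part(r, c) @ fit.trend_coefs
    parts = basis.smooth_parts(r, c)
    for nm in SMOOTH_TERMS:
        vals = vals + (parts[nm] - fit.smooth_centers[nm]) @ fit.smooth_coefs[nm]
    return pd.DataFrame({"virtual_row": r.astype(int), "virtual_range": c.astype(int),
                         "surface": vals})


# ---------------------------------------------------------------------------
# heritability and corrected values


@dataclass
class HeritabilityResult:
    """Generalized heritability from genotype effective dimension."""

    h2: float
    ed_genotype: float
    n_genotypes: int
    var_genotype: float
    var_residual: float


def heritability(fit: SpatialFit) -> HeritabilityResult:
    """``H^2 = ED_g / (n_g - 1)`` with the genotypic and residual variance
    components alongside.  Requires a genotypes-random fit."""
    if fit.mode != "random":
        raise ModeError("heritability needs a genotypes-random fit")
    ed_g = min(max(fit.eds["genotype"], 0.0), fit.n_genotypes - 1)
    return HeritabilityResult(
        h2=ed_g / (fit.n_genotypes - 1),
        ed_genotype=ed_g,
        n_genotypes=fit.n_genotypes,
        var_genotype=fit.var_components["genotype"],
        var_residual=fit.var_components["residual"],
    )


def corrected_values(fit: SpatialFit) -> pd.DataFrame:
    """Spatially corrected plot values: model intercept + genotypic BLUE +
    plot residual (surface and row effects removed).

    Requires a genotypes-fixed fit; missing plots were dropped at input and
    stay missing.
    """
    if fit.mode != "fixed":
        raise ModeError("corrected values need a genotypes-fixed fit")
    g = fit.data["genotype_id"].map(fit.genotype_effects).to_numpy(dtype=float)
    corrected = fit.intercept + g + fit.residuals
    return pd.DataFrame(
        {
            "plot_id": fit.data["plot_id"],
            "genotype_id": fit.data["genotype_id"],
            "corrected": corrected,
        }
    )


def genotype_predictions(fit: SpatialFit) -> pd.Series:
    """Per-genotype predicted values (intercept + effect), either BLUE-based
    (fixed) or BLUP-based (random)."""
    return fit.intercept + fit.genotype_effects
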