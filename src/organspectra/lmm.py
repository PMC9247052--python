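"""Per-wavelength linear mixed models and explained-variation decomposition.

For each wavelength an independent model is fitted to the annotation-level
median reflectance:

    y_ijk = alpha + organ_ijk' beta + angle_ijk' theta + delta_i + gamma_ij + eps_ijk

with fixed effects for organ (treatment coding, reference "stomach") and
angle (reference "perpendicular"), a random pig intercept
delta_i ~ N(0, sigma_pig^2), a random image-within-pig intercept
gamma_ij ~ N(0, sigma_image^2) for each recorded scene, and a repetition
residual eps_ijk ~ N(0, sigma_rep^2).  Estimation is REML.

The explained variation is decomposed empirically: the organ and angle
shares are the empirical variances (over observations) of the fitted fixed
terms, with their cross-covariance split equally between the two (it is
zero by orthogonality in balanced designs and flagged when it exceeds 1% of
the total); the pig/image/repetition shares are the REML variance
components.  Proportions are each share over the total.

Fitting engine
--------------
The default fitter exploits the nested design directly: when every image
has the same number of repetitions, an orthogonal transformation splits the
data into three independent strata (within image, between images within
pig, between pigs) with variances sigma_rep^2, sigma_rep^2 + r*sigma_image^2
and sigma_rep^2 + r*sigma_image^2 + r*m_i*sigma_pig^2.  The restricted
likelihood then reduces to weighted least squares over cached cross-product
blocks, making a fit a few milliseconds — fast enough for the parametric
bootstrap.  This is exact REML for that (possibly pig-unbalanced) layout;
data with unequal repetition counts fall back to statsmodels MixedLM.
Variance estimates are constrained non-negative (active bounds are counted
as truncations in the fit diagnostics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .hsi_core import REFERENCE_ANGLE, REFERENCE_ORGAN, SpectraTable

__all__ = [
    "FACTORS",
    "STRATIFIED_FACTORS",
    "LMMFit",
    "Decomposition",
    "VarianceDecomposition",
    "StratifiedDecomposition",
    "fit_lmm",
    "decompose",
    "decompose_table",
    "decompose_stratified",
    "bootstrap_ci",
    "bootstrap_decomposition_table",
    "median_across_wavelengths",
]

FACTORS = ("organ", "angle", "pig", "image", "repetition")
STRATIFIED_FACTORS = ("angle", "pig", "image", "repetition")

_VAR_FLOOR_REL = 1e-12


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------


def _treatment_columns(values: pd.Series, reference: str, prefix: str):
    """Treatment-coded dummy block; returns (matrix, names, row level index).

    ``row_index`` maps each row to its column in the block, -1 for the
    reference level.  A factor with a single observed level yields an empty
    block (the factor is dropped, as in stratified fits).
    """
    levels = sorted(values.unique())
    if len(levels) < 2:
        return np.empty((len(values), 0)), [], np.full(len(values), -1, dtype=int)
    if reference not in levels:
        reference = levels[0]
    nonref = [lv for lv in levels if lv != reference]
    col_of = {lv: j for j, lv in enumerate(nonref)}
    row_index = values.map(lambda v: col_of.get(v, -1)).to_numpy(dtype=int)
    mat = np.zeros((len(values), len(nonref)))
    rows = np.flatnonzero(row_index >= 0)
    mat[rows, row_index[rows]] = 1.0
    names = [f"{prefix}[{lv}]" for lv in nonref]
    return mat, names, row_index


class _NestedDesign:
    """Cached cross-product blocks for fast REML of the nested model.

    Valid when every image has the same repetition count ``r``; the number
    of images per pig may vary.
    """

    def __init__(self, X: np.ndarray, pig_codes: np.ndarray, image_codes: np.ndarray):
        n, p = X.shape
        rep_counts = np.bincount(image_codes)
        if rep_counts.min() != rep_counts.max():
            raise ValueError("unequal repetitions per image; use the MixedLM engine")
        self.r = int(rep_counts[0])
        self.n, self.p = n, p
        self.M = len(rep_counts)
        self.pig_codes = pig_codes
        self.image_codes = image_codes
        # pig of each image (nesting already validated by caller)
        img_pig = np.zeros(self.M, dtype=int)
        img_pig[image_codes] = pig_codes
        self.img_pig = img_pig
        self.P = int(pig_codes.max()) + 1
        self.m = np.bincount(img_pig, minlength=self.P).astype(float)  # images per pig
        obs_per_pig = self.r * self.m

        self.X = X
        self.XtX = X.T @ X
        Ximg = np.zeros((self.M, p))
        np.add.at(Ximg, image_codes, X)
        self.Ximg = Ximg / self.r  # image means of X rows
        self.S_img_XX = self.r * (self.Ximg.T @ self.Ximg)
        Xpig = np.zeros((self.P, p))
        np.add.at(Xpig, pig_codes, X)
        self.Xpig_mean = Xpig / obs_per_pig[:, None]
        self.sqrt_w = np.sqrt(obs_per_pig)
        self.WX = self.Xpig_mean * self.sqrt_w[:, None]
        self.S_pig_XX = self.WX.T @ self.WX

    def _aggregate_y(self, y: np.ndarray):
        y_img = np.zeros(self.M)
        np.add.at(y_img, self.image_codes, y)
        y_img /= self.r
        y_pig = np.zeros(self.P)
        np.add.at(y_pig, self.pig_codes, y)
        y_pig /= self.r * self.m
        wy = y_pig * self.sqrt_w
        return y_img, wy

    def reml_fit(self, y: np.ndarray, x0_raw: np.ndarray | None = None):
        """Return (sigma2_rep, sigma2_image, sigma2_pig, beta, converged,
        neg2reml, truncated) for response ``y``.

        ``x0_raw`` optionally warm-starts the optimizer at variances on the
        raw response scale (used by the parametric bootstrap) and skips the
        second fixed start.
        """
        scale = float(np.std(y))
        if scale <= 0:
            scale = 1.0
        ys = y / scale
        y_img, wy = self._aggregate_y(ys)
        Xty = self.X.T @ ys
        yty = float(ys @ ys)
        S_img_Xy = self.r * (self.Ximg.T @ y_img)
        S_img_yy = self.r * float(y_img @ y_img)
        S_pig_Xy = self.WX.T @ wy
        S_pig_yy = float(wy @ wy)
        r, m, p = self.r, self.m, self.p
        n, M, P = self.n, self.M, self.P
        floor = _VAR_FLOOR_REL

        def assemble(a0, a1, a2):
            inv2 = 1.0 / a2
            A = (
                (self.XtX - self.S_img_XX) / a0
                + (self.S_img_XX - self.S_pig_XX) / a1
                + (self.WX * inv2[:, None]).T @ self.WX
            )
            b = (
                (Xty - S_img_Xy) / a0
                + (S_img_Xy - S_pig_Xy) / a1
                + self.WX.T @ (inv2 * wy)
            )
            c = (
                (yty - S_img_yy) / a0
                + (S_img_yy - S_pig_yy) / a1
                + float((inv2 * wy) @ wy)
            )
            return A, b, c

        def neg2reml(params):
            s_rep, s_img, s_pig = params
            if s_rep <= 0:
                return 1e12
            a0 = s_rep
            a1 = a0 + r * s_img
            a2 = a1 + r * m * s_pig
            A, b, c = assemble(a0, a1, a2)
            try:
                beta = np.linalg.solve(A, b)
                sign, logdetA = np.linalg.slogdet(A)
            except np.linalg.LinAlgError:
                return 1e12
            if sign <= 0:
                return 1e12
            quad = max(c - b @ beta, 1e-300)
            return (
                (n - M) * np.log(a0)
                + (M - P) * np.log(a1)
                + float(np.log(a2).sum())
                + logdetA
                + quad
            )

        bounds = [(floor, None), (0.0, None), (0.0, None)]
        opts = {"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10}
        if x0_raw is not None:
            x0 = np.maximum(np.asarray(x0_raw, dtype=float) / scale**2, floor)
            res = minimize(neg2reml, x0, method="L-BFGS-B", bounds=bounds, options=opts)
        else:
            # method-of-moments start from OLS residual strata
            beta_ols, *_ = np.linalg.lstsq(self.X, ys, rcond=None)
            e = ys - self.X @ beta_ols
            e_img, we = self._aggregate_y(e)
            ss_w = max(float(e @ e) - r * float(e_img @ e_img), 0.0)
            ss_b = max(r * float(e_img @ e_img) - float(we @ we), 0.0)
            ss_p = float(we @ we)
            ms_w = ss_w / max(n - M, 1)
            ms_b = ss_b / max(M - P, 1)
            ms_p = ss_p / max(P, 1)
            s_rep0 = max(ms_w, floor)
            s_img0 = max((ms_b - ms_w) / r, floor)
            s_pig0 = max((ms_p - ms_b) / (r * float(m.mean())), floor)
            x0 = np.array([s_rep0, s_img0, s_pig0])
            res = minimize(neg2reml, x0, method="L-BFGS-B", bounds=bounds, options=opts)
            alt = minimize(
                neg2reml, np.full(3, max(np.var(ys) / 3.0, floor)),
                method="L-BFGS-B", bounds=bounds, options=opts,
            )
            if alt.fun < res.fun:
                res = alt
        s_rep, s_img, s_pig = res.x
        truncated = [
            name
            for name, v in zip(("image", "pig"), (s_img, s_pig))
            if v <= 10 * floor
        ]
        a0 = s_rep
        a1 = a0 + r * s_img
        a2 = a1 + r * m * s_pig
        A, b, _ = assemble(a0, a1, a2)
        beta = np.linalg.solve(A, b)
        converged = bool(np.isfinite(res.fun) and res.fun < 1e11)
        return (
            s_rep * scale**2,
            s_img * scale**2,
            s_pig * scale**2,
            beta * scale,
            converged,
            float(res.fun),
            truncated,
        )


# ---------------------------------------------------------------------------
# public fit API
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """REML fit of the per-wavelength mixed model."""

    alpha: float
    beta: pd.Series  # organ effects, empty when organ was dropped
    theta: pd.Series  # angle effects, empty when angle was dropped
    sigma2_pig: float
    sigma2_image: float
    sigma2_rep: float
    converged: bool
    n_obs: int
    neg2reml: float
    engine: str
    truncated: list = field(default_factory=list)
    # internals used by decompose() and bootstrap_ci()
    _design: _NestedDesign | None = field(default=None, repr=False)
    _coef: np.ndarray | None = field(default=None, repr=False)
    _organ_row_idx: np.ndarray | None = field(default=None, repr=False)
    _angle_row_idx: np.ndarray | None = field(default=None, repr=False)
    _organ_slice: slice | None = field(default=None, repr=False)
    _angle_slice: slice | None = field(default=None, repr=False)

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self._design.X @ self._coef

    def fixed_term(self, which: str, coef: np.ndarray | None = None) -> np.ndarray:
        """Per-observation organ or angle fixed-effect term."""
        coef = self._coef if coef is None else coef
        idx = self._organ_row_idx if which == "organ" else self._angle_row_idx
        sl = self._organ_slice if which == "organ" else self._angle_slice
        block = coef[sl]
        if block.size == 0:
            return np.zeros(len(idx))
        return np.where(idx >= 0, block[np.clip(idx, 0, None)], 0.0)


def _validate_frame(frame: pd.DataFrame, response: str) -> None:
    required = {"pig_id", "image_id", "organ", "angle", response}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"frame is missing columns {sorted(missing)}")
    nest = frame.groupby("image_id")["pig_id"].nunique()
    bad = nest[nest > 1]
    if len(bad):
        raise ValueError(
            f"grouping is not nested: images {list(bad.index[:3])} span several pigs"
        )


def fit_lmm(
    frame: pd.DataFrame,
    response: str = "y",
    include_organ: bool = True,
    reference_organ: str = REFERENCE_ORGAN,
    reference_angle: str = REFERENCE_ANGLE,
    engine: str = "auto",
) -> LMMFit:
    """Fit the per-wavelength mixed model by REML.

    ``frame`` needs columns ``pig_id, image_id, organ, angle`` and the
    response.  ``engine`` is ``"auto"`` (fast nested REML, falling back to
    statsmodels MixedLM for unequal repetition counts), ``"nested"`` or
    ``"mixedlm"``.  Factors with a single observed level are dropped from
    the fixed effects (stratified mode).
    """
    _validate_frame(frame, response)
    frame = frame.reset_index(drop=True)
    if frame["pig_id"].nunique() < 2:
        raise ValueError("need at least 2 pigs")
    if not (frame.groupby("pig_id")["image_id"].nunique() >= 2).any():
        raise ValueError("need at least one pig with >= 2 images")

    y = frame[response].to_numpy(dtype=float)
    organ_block, organ_names, organ_idx = (
        _treatment_columns(frame["organ"], reference_organ, "organ")
        if include_organ
        else (np.empty((len(frame), 0)), [], np.full(len(frame), -1, dtype=int))
    )
    angle_block, angle_names, angle_idx = _treatment_columns(
        frame["angle"], reference_angle, "angle"
    )
    X = np.column_stack([np.ones(len(frame)), organ_block, angle_block])
    names = ["Intercept"] + organ_names + angle_names
    organ_slice = slice(1, 1 + len(organ_names))
    angle_slice = slice(1 + len(organ_names), 1 + len(organ_names) + len(angle_names))

    pig_codes = pd.factorize(frame["pig_id"], sort=True)[0]
    image_codes = pd.factorize(frame["image_id"], sort=True)[0]

    rep_counts = np.bincount(image_codes)
    balanced_reps = rep_counts.min() == rep_counts.max()
    if engine == "nested" and not balanced_reps:
        raise ValueError("nested engine requires equal repetitions per image")
    use_nested = engine == "nested" or (engine == "auto" and balanced_reps)

    if use_nested:
        design = _NestedDesign(X, pig_codes, image_codes)
        s_rep, s_img, s_pig, coef, converged, crit, truncated = design.reml_fit(y)
        used_engine = "nested"
    elif engine in ("auto", "mixedlm"):
        s_rep, s_img, s_pig, coef, converged, crit, truncated = _fit_mixedlm(
            frame, response, X, names
        )
        design = _NestedDesign.__new__(_NestedDesign)  # minimal holder for X
        design.X = X
        used_engine = "mixedlm"
    else:
        raise ValueError(f"unknown engine {engine!r}")

    fit = LMMFit(
        alpha=float(coef[0]),
        beta=pd.Series(coef[organ_slice], index=organ_names, dtype=float),
        theta=pd.Series(coef[angle_slice], index=angle_names, dtype=float),
        sigma2_pig=float(s_pig),
        sigma2_image=float(s_img),
        sigma2_rep=float(s_rep),
        converged=converged,
        n_obs=len(frame),
        neg2reml=float(crit),
        engine=used_engine,
        truncated=truncated,
    )
    fit._design = design
    fit._coef = np.asarray(coef, dtype=float)
    fit._organ_row_idx = organ_idx
    fit._angle_row_idx = angle_idx
    fit._organ_slice = organ_slice
    fit._angle_slice = angle_slice
    return fit


def _fit_mixedlm(frame: pd.DataFrame, response: str, X: np.ndarray, names: list[str]):
    """statsmodels MixedLM fallback for unequal repetition counts.

    The formula is assembled so that the fixed-effect coefficient order
    (intercept, sorted non-reference organs, sorted non-reference angles)
    matches the in-package design matrix.
    """
    import statsmodels.formula.api as smf

    data = frame.copy()
    data["_y"] = frame[response].to_numpy(dtype=float)
    terms = []
    for col, prefix in (("organ", "organ"), ("angle", "angle")):
        if any(n.startswith(f"{prefix}[") for n in names):
            nonref = {n[len(prefix) + 1 : -1] for n in names if n.startswith(f"{prefix}[")}
            ref = sorted(set(data[col]) - nonref)[0]
            terms.append(f"C({col}, Treatment('{ref}'))")
    formula = "_y ~ " + (" + ".join(terms) if terms else "1")
    model = smf.mixedlm(
        formula, data, groups=data["pig_id"], re_formula="1",
        vc_formula={"image": "0 + C(image_id)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    s_pig = float(np.asarray(res.cov_re)[0, 0])
    s_img = float(res.vcomp[0])
    s_rep = float(res.scale)
    coef = res.fe_params.to_numpy()
    if len(coef) != len(names):
        raise RuntimeError("MixedLM coefficient layout mismatch")
    return s_rep, s_img, s_pig, coef, bool(res.converged), float(-2 * res.llf), []


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------


@dataclass
class Decomposition:
    proportions: dict[str, float]
    components: dict[str, float]
    cross_term_share: float


def _components_from(
    organ_term: np.ndarray, angle_term: np.ndarray, s_pig, s_img, s_rep
):
    v_organ = float(organ_term.var())
    v_angle = float(angle_term.var())
    cross = float(np.cov(organ_term, angle_term, ddof=0)[0, 1]) if len(organ_term) else 0.0
    comps = {
        "organ": v_organ + cross,
        "angle": v_angle + cross,
        "pig": float(s_pig),
        "image": float(s_img),
        "repetition": float(s_rep),
    }
    return comps, cross


def decompose(fit: LMMFit) -> Decomposition:
    """Empirical explained-variation decomposition of a converged fit.

    Organ/angle shares are empirical variances of the fitted fixed terms
    over the observations; their cross-covariance is split equally and
    flagged if it exceeds 1% of the total variation.
    """
    if not fit.converged:
        raise ValueError("cannot decompose a non-converged fit")
    organ_term = fit.fixed_term("organ")
    angle_term = fit.fixed_term("angle")
    comps, cross = _components_from(
        organ_term, angle_term, fit.sigma2_pig, fit.sigma2_image, fit.sigma2_rep
    )
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("no variation: all components are zero")
    share = abs(2 * cross) / total
    if share > 0.01:
        warnings.warn(
            f"organ/angle cross-covariance is {share:.1%} of total variation; "
            "equal-split allocation may matter"
        )
    return Decomposition(
        proportions={k: v / total for k, v in comps.items()},
        components=comps,
        cross_term_share=share,
    )


def _stratified_sds(fit: LMMFit) -> dict[str, float]:
    angle_term = fit.fixed_term("angle")
    return {
        "angle": float(angle_term.std()),
        "pig": float(np.sqrt(fit.sigma2_pig)),
        "image": float(np.sqrt(fit.sigma2_image)),
        "repetition": float(np.sqrt(fit.sigma2_rep)),
    }


@dataclass
class VarianceDecomposition:
    """Per-wavelength explained-variation proportions, with optional CIs."""

    proportions: pd.DataFrame  # index wavelength_nm, columns FACTORS
    ci_lo: pd.DataFrame | None = None
    ci_hi: pd.DataFrame | None = None
    nonconverged: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("proportions must sum to 1 per wavelength")

    def medians(self) -> dict[str, float]:
        return {f: float(self.proportions[f].median()) for f in self.proportions.columns}

    def to_long_csv(self, path) -> None:
        long = self.proportions.reset_index().melt(
            id_vars="wavelength_nm", var_name="factor", value_name="estimate"
        )
        if self.ci_lo is not None:
            lo = self.ci_lo.reset_index().melt(
                id_vars="wavelength_nm", var_name="factor", value_name="ci_lo"
            )
            hi = self.ci_hi.reset_index().melt(
                id_vars="wavelength_nm", var_name="factor", value_name="ci_hi"
            )
            long = long.merge(lo, on=["wavelength_nm", "factor"]).merge(
                hi, on=["wavelength_nm", "factor"]
            )
        long.to_csv(path, index=False)


@dataclass
class StratifiedDecomposition:
    """Per-wavelength explained SDs for one organ (model without organ)."""

    organ: str
    sds: pd.DataFrame  # index wavelength_nm, columns STRATIFIED_FACTORS
    ci_lo: pd.DataFrame | None = None
    ci_hi: pd.DataFrame | None = None
    nonconverged: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sds) and (self.sds.to_numpy() < 0).any():
            raise ValueError("explained SDs must be non-negative")

    def medians(self) -> dict[str, float]:
        return {f: float(self.sds[f].median()) for f in self.sds.columns}


def _frame_at_band(table: SpectraTable, band: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pig_id": table.df["pig_id"],
            "image_id": table.df["image_id"],
            "organ": table.df["organ"],
            "angle": table.df["angle"],
            "y": table.df[band].to_numpy(dtype=float),
        }
    )


def decompose_table(table: SpectraTable, engine: str = "auto") -> VarianceDecomposition:
    """Fit the pooled model at every wavelength and decompose each fit.

    Non-convergent wavelengths are reported as gaps (listed in
    ``nonconverged``), never interpolated.
    """
    rows, bad = {}, []
    for nm, band in zip(table.wavelengths, table.grid.band_columns):
        fit = fit_lmm(_frame_at_band(table, band), engine=engine)
        if not fit.converged:
            bad.append(float(nm))
            continue
        rows[float(nm)] = decompose(fit).proportions
    props = pd.DataFrame.from_dict(rows, orient="index", columns=list(FACTORS))
    props.index.name = "wavelength_nm"
    return VarianceDecomposition(props, nonconverged=bad)


def decompose_stratified(
    table: SpectraTable, organ: str, engine: str = "auto"
) -> StratifiedDecomposition:
    """Explained SDs per wavelength for one organ (no organ fixed effect)."""
    sub = table.subset(table.df["organ"] == organ)
    if sub.df["pig_id"].nunique() < 2:
        raise ValueError(f"need >= 2 pigs with organ {organ!r}")
    rows, bad = {}, []
    for nm, band in zip(sub.wavelengths, sub.grid.band_columns):
        fit = fit_lmm(_frame_at_band(sub, band), include_organ=False, engine=engine)
        if not fit.converged:
            bad.append(float(nm))
            continue
        rows[float(nm)] = _stratified_sds(fit)
    sds = pd.DataFrame.from_dict(rows, orient="index", columns=list(STRATIFIED_FACTORS))
    sds.index.name = "wavelength_nm"
    return StratifiedDecomposition(organ, sds, nonconverged=bad)


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    fit: LMMFit,
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
    stratified: bool = False,
    max_nonconvergence: float = 0.2,
):
    """Percentile bootstrap bands from ``B`` parametric resamples.

    Each resample redraws the random pig, image and repetition terms from
    the fitted variances on top of the fitted fixed part, refits, and
    re-decomposes.  Returns ``{factor: (lo, hi)}``; raises if more than
    ``max_nonconvergence`` of the refits fail.
    """
    if fit.engine != "nested" or fit._design is None or not hasattr(fit._design, "pig_codes"):
        raise ValueError("bootstrap_ci requires a fit from the nested engine")
    design = fit._design
    rng = np.random.default_rng(seed)
    mu = fit.fitted_fixed
    s_pig, s_img, s_rep = np.sqrt([fit.sigma2_pig, fit.sigma2_image, fit.sigma2_rep])
    factors = STRATIFIED_FACTORS if stratified else FACTORS
    samples = np.full((B, len(factors)), np.nan)
    failures = 0
    for b in range(B):
        ystar = (
            mu
            + (rng.normal(size=design.P) * s_pig)[design.pig_codes]
            + (rng.normal(size=design.M) * s_img)[design.image_codes]
            + rng.normal(size=design.n) * s_rep
        )
        rep_s, img_s, pig_s, coef, converged, _, _ = design.reml_fit(
            ystar, x0_raw=np.array([fit.sigma2_rep, fit.sigma2_image, fit.sigma2_pig])
        )
        if not converged:
            failures += 1
            continue
        organ_term = fit.fixed_term("organ", coef)
        angle_term = fit.fixed_term("angle", coef)
        if stratified:
            samples[b] = [
                float(angle_term.std()),
                np.sqrt(pig_s),
                np.sqrt(img_s),
                np.sqrt(rep_s),
            ]
        else:
            comps, _ = _components_from(organ_term, angle_term, pig_s, img_s, rep_s)
            total = sum(comps.values())
            samples[b] = [comps[f] / total for f in factors]
    if failures > max_nonconvergence * B:
        raise RuntimeError(
            f"bootstrap non-convergence rate {failures / B:.1%} exceeds "
            f"{max_nonconvergence:.0%}"
        )
    ok = samples[~np.isnan(samples).any(axis=1)]
    alpha = (1.0 - level) / 2
    lo = np.percentile(ok, 100 * alpha, axis=0)
    hi = np.percentile(ok, 100 * (1 - alpha), axis=0)
    return {f: (float(lo[j]), float(hi[j])) for j, f in enumerate(factors)}


def bootstrap_decomposition_table(
    table: SpectraTable, B: int = 500, level: float = 0.95, seed: int = 0
) -> VarianceDecomposition:
    """Pooled decomposition with per-wavelength bootstrap confidence bands."""
    rows, lo_rows, hi_rows, bad = {}, {}, {}, []
    for k, (nm, band) in enumerate(zip(table.wavelengths, table.grid.band_columns)):
        fit = fit_lmm(_frame_at_band(table, band))
        if not fit.converged:
            bad.append(float(nm))
            continue
        rows[float(nm)] = decompose(fit).proportions
        ci = bootstrap_ci(fit, B=B, level=level, seed=seed + k)
        lo_rows[float(nm)] = {f: ci[f][0] for f in FACTORS}
        hi_rows[float(nm)] = {f: ci[f][1] for f in FACTORS}
    props = pd.DataFrame.from_dict(rows, orient="index", columns=list(FACTORS))
    props.index.name = "wavelength_nm"
    lo = pd.DataFrame.from_dict(lo_rows, orient="index", columns=list(FACTORS))
    lo.index.name = "wavelength_nm"
    hi = pd.DataFrame.from_dict(hi_rows, orient="index", columns=list(FACTORS))
    hi.index.name = "wavelength_nm"
    return VarianceDecomposition(props, ci_lo=lo, ci_hi=hi, nonconverged=bad)


def median_across_wavelengths(decomp) -> dict[str, float]:
    """Per-factor median across wavelengths of a decomposition."""
    return decomp.medians()
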