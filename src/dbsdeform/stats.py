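"""Cohort-level statistics: ICC, Sidak correction, mixed-model contrasts.

Regional deformation parameters are correlated within a patient (two
hemispheres x three layers), so between-group effects are assessed with a
mixed linear model: fixed effects electrode type, hemisphere, tissue layer
and their interactions, and a patient random intercept, fitted by REML.
Between-patient and residual variance components give the intraclass
correlation ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2), classified low
(< 0.6), moderate (0.6-0.8) or high (> 0.8).  Pairwise contrasts are
grouped into families (layer pairs within each hemisphere; right-vs-left
within each layer) and Sidak-corrected within each family.  A thin
normality-gated two-sample comparison (Student's t when Shapiro-Wilk and
the F variance-ratio test both pass, Mann-Whitney otherwise) covers
between-group checks on independent rows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    ModelFailureError,
    UndefinedICCError,
)
from .regional import BRAIN_LAYERS

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class VarianceComponents:
    """Between-patient and residual variances (parameter units squared)."""

    between_patient_var: float
    residual_var: float

    def __post_init__(self):
        if self.between_patient_var < 0 or self.residual_var < 0:
            raise InvalidArgumentError("variance components must be >= 0")


@dataclass
class ContrastResult:
    """One pairwise fixed-effect contrast with its Sidak-adjusted p-value."""

    family: str
    description: str
    estimate: float
    units: str
    se: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float
    family_size: int
    significant: bool


@dataclass
class GroupComparison:
    """Outcome of the normality-gated two-sample comparison."""

    test_name: str
    statistic: float
    p_value: float
    normal_a: bool
    normal_b: bool
    equal_variance: bool


def icc_classify(components: VarianceComponents) -> tuple[float, str]:
    """ICC = between / (between + residual), with threshold classification."""
    total = components.between_patient_var + components.residual_var
    if total <= 0:
        raise UndefinedICCError("both variance components are zero; ICC undefined")
    icc = components.between_patient_var / total
    if icc < 0.6:
        cls = "low"
    elif icc <= 0.8:
        cls = "moderate"
    else:
        cls = "high"
    return icc, cls


def sidak_alpha(alpha: float, m: int) -> float:
    """Per-test alpha 1 - (1 - alpha)^(1/m) controlling family-wise error."""
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise InvalidArgumentError(f"number of comparisons must be >= 1, got {m}")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak-adjusted p-value 1 - (1 - p)^m (compared against raw alpha)."""
    if m < 1:
        raise InvalidArgumentError(f"number of comparisons must be >= 1, got {m}")
    return float(1.0 - (1.0 - min(max(p, 0.0), 1.0)) ** m)


# --------------------------------------------------------------------------
# mixed-model layer/hemisphere contrasts
# --------------------------------------------------------------------------

_REQUIRED_COLS = ("patient", "hemisphere", "layer", "electrode_type")


@dataclass
class LayerContrastReport:
    """Contrasts, variance components and fit metadata for one parameter."""

    parameter: str
    contrasts: list[ContrastResult]
    components: VarianceComponents
    icc: float
    icc_class: str
    log_transformed: bool
    residual_shapiro_p: float
    metadata: dict = field(default_factory=dict)


def _cell_row(design_info, etype, hemisphere, layer) -> np.ndarray:
    from patsy import build_design_matrices

    df = pd.DataFrame(
        {"electrode_type": [etype], "hemisphere": [hemisphere], "layer": [layer]}
    )
    return np.asarray(build_design_matrices([design_info], df)[0])[0]


def _fit_mixedlm(data: pd.DataFrame, response: str):
    import statsmodels.formula.api as smf

    formula = f"{response} ~ C(electrode_type) * C(hemisphere) * C(layer)"
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["patient"])
        # optimizer robustness: some surfaces defeat the default gradient path
        for method in (None, "powell", "cg"):
            try:
                kwargs = {"reml": True}
                if method is not None:
                    kwargs["method"] = method
                return model, model.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
    raise last_exc


def layer_contrasts(
    cohort: pd.DataFrame, parameter: str, alpha: float = DEFAULT_ALPHA
) -> LayerContrastReport:
    """Random-intercept model of one regional parameter with contrast families.

    Fits ``parameter ~ type * hemisphere * layer`` with a patient random
    intercept (REML).  If model residuals fail Shapiro-Wilk normality at
    0.05 the response is log-transformed (with an offset making it
    positive) and refitted; estimates are then on the log scale and flagged.
    Emits pairwise tissue-layer contrasts within each hemisphere and
    right-vs-left contrasts within each layer, each family Sidak-corrected,
    with contrasts taken on cell means averaged over electrode type.
    """
    for col in _REQUIRED_COLS:
        if col not in cohort.columns:
            raise InvalidArgumentError(f"cohort table lacks required column '{col}'")
    if parameter not in cohort.columns:
        raise InvalidArgumentError(f"unknown parameter column '{parameter}'")
    data = cohort.dropna(subset=[parameter]).copy()
    if data["patient"].nunique() < 2:
        raise InsufficientDataError("need at least 2 patients")
    cells = data.groupby(["hemisphere", "layer"], observed=True).size()
    if len(cells) < 6:
        raise InsufficientDataError("incomplete hemisphere x layer cells")

    response = parameter
    log_transformed = False
    offset = 0.0
    try:
        model, result = _fit_mixedlm(data, response)
    except Exception as exc:  # singular design, convergence failure
        raise ModelFailureError(f"mixed-model fit failed for '{parameter}': {exc}") from exc

    resid = np.asarray(result.resid, dtype=float)
    shapiro_p = float(sps.shapiro(resid).pvalue) if len(resid) <= 5000 else 1.0
    if shapiro_p < 0.05:
        vals = data[parameter].to_numpy(dtype=float)
        offset = float(max(0.0, -vals.min()) + max(vals.std(), 1e-6))
        data["_log_response"] = np.log(vals + offset)
        try:
            model, result = _fit_mixedlm(data, "_log_response")
            log_transformed = True
        except Exception as exc:
            raise ModelFailureError(
                f"mixed-model fit failed for log({parameter}): {exc}"
            ) from exc

    between = float(np.asarray(result.cov_re)[0, 0])
    residual = float(result.scale)
    components = VarianceComponents(max(between, 0.0), residual)
    icc, icc_class = icc_classify(components)

    design_info = model.data.design_info
    etypes = sorted(data["electrode_type"].unique())
    layers = [l for l in BRAIN_LAYERS if l in set(data["layer"])]
    hemis = [h for h in ("right", "left") if h in set(data["hemisphere"])]
    units = "log units" if log_transformed else "parameter units"

    def cell_mean_row(hemisphere, layer):
        rows = [_cell_row(design_info, e, hemisphere, layer) for e in etypes]
        return np.mean(rows, axis=0)

    families: list[tuple[str, list[tuple[str, np.ndarray]]]] = []
    for hemi in hemis:
        fam = []
        for la, lb in itertools.combinations(layers, 2):
            vec = cell_mean_row(hemi, la) - cell_mean_row(hemi, lb)
            fam.append((f"{la} - {lb} | {hemi}", vec))
        families.append((f"layers_within_{hemi}", fam))
    if len(hemis) == 2:
        fam = []
        for layer in layers:
            vec = cell_mean_row(hemis[0], layer) - cell_mean_row(hemis[1], layer)
            fam.append((f"{hemis[0]} - {hemis[1]} | {layer}", vec))
        families.append(("hemispheres_within_layer", fam))

    contrasts = []
    for family_name, members in families:
        m = len(members)
        for desc, vec in members:
            tt = result.t_test(vec.reshape(1, -1))
            est = float(np.squeeze(tt.effect))
            se = float(np.squeeze(tt.sd))
            p_raw = float(np.squeeze(tt.pvalue))
            ci = tt.conf_int(alpha)
            p_adj = sidak_adjust(p_raw, m)
            contrasts.append(
                ContrastResult(
                    family=family_name,
                    description=desc,
                    estimate=est,
                    units=units,
                    se=se,
                    ci_low=float(np.squeeze(ci)[0]),
                    ci_high=float(np.squeeze(ci)[1]),
                    p_raw=p_raw,
                    p_adjusted=p_adj,
                    family_size=m,
                    significant=bool(p_adj < alpha),
                )
            )

    return LayerContrastReport(
        parameter=parameter,
        contrasts=contrasts,
        components=components,
        icc=icc,
        icc_class=icc_class,
        log_transformed=log_transformed,
        residual_shapiro_p=shapiro_p,
        metadata={
            "alpha": alpha,
            "families": {name: len(members) for name, members in families},
            "log_offset": offset,
            "n_rows": int(len(data)),
            "n_patients": int(data["patient"].nunique()),
        },
    )


def group_compare(sample_a, sample_b, alpha: float = DEFAULT_ALPHA) -> GroupComparison:
    """Student's t-test or Mann-Whitney, gated on the t-test's requirements.

    Normality is assessed per sample by Shapiro-Wilk at 0.05 and decides
    parametric vs rank; the F variance-ratio (Fisher-Snedecor) test decides
    the pooled vs Welch flavour of the parametric path.  Both decisions are
    recorded in the output.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each sample needs at least 3 observations")

    def _normal(x):
        if np.ptp(x) == 0:
            return False  # degenerate sample: Shapiro undefined
        return bool(sps.shapiro(x).pvalue >= 0.05)

    normal_a, normal_b = _normal(a), _normal(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 or vb <= 0:
        equal_var = va == vb
    else:
        f = max(va, vb) / min(va, vb)
        dfn = (a.size if va >= vb else b.size) - 1
        dfd = (b.size if va >= vb else a.size) - 1
        p_f = 2.0 * min(sps.f.sf(f, dfn, dfd), 1.0 - sps.f.sf(f, dfn, dfd))
        equal_var = p_f >= 0.05

    if normal_a and normal_b:
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return GroupComparison(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        normal_a=normal_a,
        normal_b=normal_b,
        equal_variance=equal_var,
    )
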