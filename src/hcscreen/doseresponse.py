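"""Four-parameter logistic (4PL) dose-response analysis.

Responses are percentages of an untreated (PBS) control; the top
asymptote is therefore pinned at 100% while the bottom plateau, the
IC50 and the Hill slope are free.  Potency is reported as
pIC50 = -log10(molar IC50), so a concentration in uM maps through
pIC50 = 6 - log10(IC50_uM).  Confidence intervals are asymptotic
normal intervals from the least-squares covariance.

Mixtures at a fixed molar ratio are dosed on the axis of the reference
(first-listed, chemotherapy) component; the co-components' series
follow from their ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

DEFAULT_DILUTION_FACTOR = 6.0


@dataclass(frozen=True)
class TreatmentCondition:
    """A compound or fixed-ratio mixture and its dilution design.

    ``components`` lists (name, molar_ratio) pairs; the first entry is
    the reference component (ratio conventionally 1) whose concentration
    defines the dose axis.
    """

    components: Tuple[Tuple[str, float], ...]
    top_concentration: float  # uM of the reference component
    dilution_factor: float = DEFAULT_DILUTION_FACTOR
    n_points: int = 8

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one component required")
        if any(r <= 0 for _, r in self.components):
            raise ValueError("molar ratios must be positive")
        if self.top_concentration <= 0:
            raise ValueError(
                f"top_concentration must be positive, got {self.top_concentration}"
            )
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def name(self) -> str:
        parts = [n for n, _ in self.components]
        if len(parts) == 1:
            return parts[0]
        ratios = ":".join(f"{r:g}" for _, r in self.components)
        return "+".join(parts) + f" ({ratios})"


@dataclass
class DoseResponseCurve:
    """Replicate-resolved normalized responses along a dilution series."""

    concentrations: np.ndarray  # uM of the reference component, per observation
    responses: np.ndarray  # % of control, per observation
    condition: str = ""
    control_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass
class DoseResponseFit:
    pic50: float
    pic50_ci95: Tuple[float, float]
    bottom: float
    bottom_ci95: Tuple[float, float]
    hill: float
    top: float
    converged: bool
    status: str
    rss: float
    se_pic50: float = float("nan")
    se_bottom: float = float("nan")
    n_obs: int = 0
    condition: str = ""


def four_param_logistic(conc, bottom, top, pic50, hill):
    """4PL response at concentration ``conc`` (uM).

    R(c) = bottom + (top - bottom) / (1 + 10^(hill * (log10 c - log10 IC50))),
    with IC50 expressed through pIC50 (molar scale).  Positive ``hill``
    gives a response falling from ``top`` toward ``bottom`` with dose.
    """
    log_c = np.log10(np.asarray(conc, dtype=float))
    log_ic50_um = 6.0 - pic50
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log_ic50_um)))


def make_dilution_series(cond: TreatmentCondition) -> Dict[str, np.ndarray]:
    """Concentration series (uM) per component, reference first.

    The reference series is top/f^(i-1); each co-component's series is
    the reference series scaled by its molar ratio relative to the
    reference component's ratio.
    """
    ref_name, ref_ratio = cond.components[0]
    ref = cond.top_concentration / cond.dilution_factor ** np.arange(cond.n_points)
    return {name: ref * (ratio / ref_ratio) for name, ratio in cond.components}


def normalize_to_control(values, control_values) -> np.ndarray:
    """Express raw measurements as % of the mean untreated control."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    mean = control.mean()
    if not mean > 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    return values / mean * 100.0


def fit_4pl(curve: DoseResponseCurve, top_fixed: float = 100.0) -> DoseResponseFit:
    """Least-squares 4PL fit with the top asymptote fixed.

    Requires >= 4 distinct positive concentrations (zero-dose controls
    are for normalization, not fitting).  Non-convergence — including a
    flat, no-dose-effect curve whose IC50 is unidentifiable — is
    surfaced through ``converged``/``status``, never as fabricated
    parameters.
    """
    pos = curve.concentrations > 0
    conc = curve.concentrations[pos]
    resp = curve.responses[pos]
    distinct = np.unique(conc)
    if distinct.size < 4:
        raise ValueError(
            f"need >= 4 distinct positive concentrations, got {distinct.size}"
        )

    log_c = np.log10(conc)

    def model(lc, bottom, pic50, hill):
        return bottom + (top_fixed - bottom) / (
            1.0 + 10.0 ** (hill * (lc - (6.0 - pic50)))
        )

    # initial guesses: bottom from the low tail, pIC50 from the half-way crossing
    bottom0 = float(np.clip(resp.min(), -50.0, top_fixed - 1.0))
    half = (top_fixed + bottom0) / 2.0
    order = np.argsort(log_c)
    crossing = log_c[order][np.argmin(np.abs(resp[order] - half))]
    p0 = (bottom0, 6.0 - crossing, 1.0)
    lo = (-100.0, 6.0 - (log_c.max() + 3.0), 0.01)
    hi = (top_fixed, 6.0 - (log_c.min() - 3.0), 20.0)

    def _fail(msg: str) -> DoseResponseFit:
        return DoseResponseFit(
            pic50=float("nan"), pic50_ci95=(float("nan"), float("nan")),
            bottom=float("nan"), bottom_ci95=(float("nan"), float("nan")),
            hill=float("nan"), top=top_fixed, converged=False, status=msg,
            rss=float("nan"), n_obs=int(conc.size), condition=curve.condition,
        )

    try:
        popt, pcov = optimize.curve_fit(
            model, log_c, resp, p0=p0, bounds=(lo, hi), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return _fail(f"least-squares did not converge: {exc}")

    bottom, pic50, hill = (float(v) for v in popt)
    resid = resp - model(log_c, *popt)
    rss = float(np.sum(resid ** 2))
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.inf)
    se_bottom, se_pic50, _ = (float(v) for v in perr)

    if not all(np.isfinite(v) for v in (bottom, pic50, hill)):
        return _fail("non-finite parameter estimates")
    # a fitted amplitude buried in the residual noise means the curve is
    # flat over the tested range and the IC50 is meaningless
    dof = max(conc.size - 3, 1)
    resid_sd = np.sqrt(rss / dof)
    if (top_fixed - bottom) < 3.0 * resid_sd:
        return _fail("no measurable dose effect: fitted amplitude "
                     f"{top_fixed - bottom:.2g} below residual noise "
                     f"({resid_sd:.2g})")

    z = stats.t.ppf(0.975, dof)  # small-sample critical value
    return DoseResponseFit(
        pic50=pic50,
        pic50_ci95=(pic50 - z * se_pic50, pic50 + z * se_pic50),
        bottom=bottom,
        bottom_ci95=(bottom - z * se_bottom, bottom + z * se_bottom),
        hill=hill,
        top=top_fixed,
        converged=True,
        status="ok",
        rss=rss,
        se_pic50=se_pic50,
        se_bottom=se_bottom,
        n_obs=int(conc.size),
        condition=curve.condition,
    )


def pIC50_to_IC50(pic50: float) -> float:
    """IC50 in uM from pIC50 (negative log10 of the molar IC50)."""
    return 10.0 ** (-float(pic50)) * 1e6


def compare_pIC50(fit_a: DoseResponseFit, fit_b: DoseResponseFit
                  ) -> Tuple[float, float, float]:
    """Two-sided z-comparison of two fitted potencies.

    Returns (difference a-b, z statistic, p value); standard errors come
    from the fits' 95% CIs.  Plumbing for the question "is the mixture
    more potent than its components?", not a replacement for a designed
    multiple-comparison analysis.
    """
    for f in (fit_a, fit_b):
        if not f.converged or not np.isfinite(f.se_pic50) or f.se_pic50 <= 0:
            raise ValueError("compare_pIC50 requires converged fits with finite SEs")
    diff = fit_a.pic50 - fit_b.pic50
    se = float(np.hypot(fit_a.se_pic50, fit_b.se_pic50))
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return diff, z, p
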