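"""TEVC protocol segmentation, % inhibition, and dose-response fitting.

Three inhibition models are supported (x = drug concentration in mM):

* ``one_site`` — the one-component binding isotherm
  ``%inh = 100 x / (x + Kd_app)``;
* ``hill`` — the one-site Hill equation
  ``%inh = 100 x^n / (x^n + Kd_app^n)``;
* ``two_site`` — the two-component isotherm
  ``%inh = 100 c x / (x + Kd1_app) + 100 (1 - c) x / (x + Kd2_app)``,
  with ``c`` the high-affinity fraction.

GIRK current at any protocol step is the step current minus the current
under Ba2+ block (which removes all GIRK current and reveals the non-GIRK
leak); % inhibition at concentration x is measured against the drug-free
HK24 GIRK current.  Fits are ordinary least squares with multi-start
initialisation and report asymptotic standard errors, the residual sum of
squares and the small-sample corrected information criterion (AICc) for
model comparison — no automatic winner is declared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .types import ActivationFitParams, DoseFitParams, TEVCTrace


@dataclass(frozen=True)
class SteadyStateParams:
    """Averaging window for per-segment steady-state currents."""

    window: float = 5.0  # s, averaged at the end of each segment
    switch_guard: float = 1.0  # s excluded after each solution switch


def segment_steady_state(
    trace: TEVCTrace, params: SteadyStateParams | None = None
) -> list[tuple[str, float, float]]:
    """Mean current over the final window of every protocol segment.

    Returns ``(label, conc_mM, current_uA)`` per segment.  The window is
    clipped so it never reaches into the first ``switch_guard`` seconds
    after the solution switch; a window longer than any segment is an error.
    """
    if params is None:
        params = SteadyStateParams()
    shortest = min(s.length for s in trace.protocol)
    if params.window > shortest:
        raise ValueError(
            f"window {params.window:g} s exceeds shortest segment ({shortest:g} s)"
        )
    out = []
    for seg in trace.protocol:
        lo = max(seg.end - params.window, seg.start + params.switch_guard)
        mask = (trace.time >= lo) & (trace.time < seg.end)
        if not mask.any():
            raise ValueError(f"no samples in steady-state window of segment {seg.label}")
        out.append((seg.label, seg.conc_mM, float(trace.current[mask].mean())))
    return out


def percent_inhibition(
    segment_currents: list[tuple[str, float, float]]
) -> list[tuple[float, float]]:
    """Dose-response points (conc_mM, % inhibition) from segment currents.

    Requires a plain HK24 reference, at least one ETX segment and the BA
    segment.  Values outside [0, 100] are permitted (noise) and not clamped.
    """
    by_label = {}
    etx = []
    for label, conc, cur in segment_currents:
        if label == "ETX":
            etx.append((conc, cur))
        else:
            by_label[label] = cur
    if "HK24" not in by_label or "BA" not in by_label or not etx:
        raise ValueError("need HK24 reference, >=1 ETX segment and BA segment")
    i_ba = by_label["BA"]
    girk_ref = by_label["HK24"] - i_ba
    if girk_ref == 0:
        raise ValueError("no measurable GIRK current (HK24 equals Ba2+ level)")
    return [
        (conc, 100.0 * (1.0 - (cur - i_ba) / girk_ref)) for conc, cur in sorted(etx)
    ]


# ---------------------------------------------------------------------------
# Models

_MODEL_PARAMS = {
    "one_site": ("kd_app",),
    "hill": ("kd_app", "n_h"),
    "two_site": ("c", "kd1_app", "kd2_app"),
}


def _model_fn(model: str):
    if model == "one_site":
        return lambda x, kd: 100.0 * x / (x + kd)
    if model == "hill":
        return lambda x, kd, n: 100.0 * x**n / (x**n + kd**n)
    if model == "two_site":
        return lambda x, c, kd1, kd2: (
            100.0 * c * x / (x + kd1) + 100.0 * (1.0 - c) * x / (x + kd2)
        )
    raise ValueError(f"unknown dose-response model {model!r}")


def eval_model(model: str, params: DoseFitParams, x) -> np.ndarray | float:
    """Evaluate an inhibition model at concentration(s) x (mM).

    Strictly increasing in x for valid parameters, 0 at x = 0 and bounded
    by 100; negative concentrations are an error.
    """
    xarr = np.asarray(x, float)
    if np.any(xarr < 0):
        raise ValueError("concentrations must be >= 0")
    fn = _model_fn(model)
    if model == "one_site":
        out = fn(xarr, params.kd_app)
    elif model == "hill":
        out = fn(xarr, params.kd_app, params.n_h)
    else:
        out = fn(xarr, params.c, params.kd1_app, params.kd2_app)
    return float(out) if np.isscalar(x) else out


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    k counts the model's free parameters plus the noise variance.
    """
    k = k + 1
    if n <= k + 1 or rss <= 0:
        return float("nan")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _starts(model: str, conc: np.ndarray) -> list[list[float]]:
    """Multi-start initialisation grid spanning the tested concentrations."""
    kd_grid = np.geomspace(conc.min(), conc.max(), 5)
    if model == "one_site":
        return [[kd] for kd in kd_grid]
    if model == "hill":
        return [[kd, n] for kd in kd_grid for n in (0.5, 1.0, 2.0)]
    return [
        [c, kd1, kd2]
        for c in (0.2, 0.5, 0.8)
        for kd1 in kd_grid[:3]
        for kd2 in kd_grid[2:]
        if kd1 < kd2
    ]


def fit_model(
    conc: np.ndarray,
    inhibition: np.ndarray,
    model: str = "one_site",
) -> DoseFitParams:
    """Least-squares fit of an inhibition model to dose-response points.

    Multi-start initialisation over a geometric Kd grid (and coarse n / c
    grids); bounds keep dissociation constants and the Hill coefficient
    positive and c in [0, 1].  Raises if no start converges.
    """
    conc = np.asarray(conc, float)
    y = np.asarray(inhibition, float)
    names = _MODEL_PARAMS[model]
    if conc.size < len(names) + 1:
        raise ValueError(f"{model} needs at least {len(names) + 1} points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive for fitting")
    fn = _model_fn(model)
    eps = 1e-12
    if model == "one_site":
        bounds = ([eps], [np.inf])
    elif model == "hill":
        bounds = ([eps, eps], [np.inf, np.inf])
    else:
        bounds = ([0.0, eps, eps], [1.0, np.inf, np.inf])

    best = None
    best_rss = np.inf
    for p0 in _starts(model, conc):
        try:
            popt, pcov = curve_fit(
                fn, conc, y, p0=p0, bounds=bounds, maxfev=20000, xtol=1e-12, ftol=1e-12
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((fn(conc, *popt) - y) ** 2))
        if rss < best_rss - 1e-10 or best is None:
            best, best_pcov, best_rss = popt, pcov, rss
    if best is None:
        raise RuntimeError(f"{model} fit did not converge from any start")

    stderr = {}
    if conc.size > len(names):
        # curve_fit's pcov is already scaled by the residual variance
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.clip(np.diag(best_pcov), 0, None))
        stderr = {n_: float(s) for n_, s in zip(names, se)}

    fields = dict(zip(names, (float(v) for v in best)))
    if model == "two_site" and fields["kd1_app"] > fields["kd2_app"]:
        # canonical order: site 1 is the high-affinity (smaller Kd) site
        fields["kd1_app"], fields["kd2_app"] = fields["kd2_app"], fields["kd1_app"]
        fields["c"] = 1.0 - fields["c"]
        s1, s2 = stderr.get("kd1_app"), stderr.get("kd2_app")
        if s1 is not None and s2 is not None:
            stderr["kd1_app"], stderr["kd2_app"] = s2, s1
    return DoseFitParams(
        model=model,
        stderr=stderr,
        rss=best_rss,
        aicc=_aicc(best_rss, conc.size, len(names)),
        n_points=int(conc.size),
        **fields,
    )


def fit_all_models(conc: np.ndarray, inhibition: np.ndarray) -> list[DoseFitParams]:
    """Fit the three standard models to the same points."""
    return [fit_model(conc, inhibition, m) for m in ("one_site", "hill", "two_site")]


def fit_activation_hill(surface: np.ndarray, currents: np.ndarray) -> ActivationFitParams:
    """Hill activation fit I = Imax G^4 / (G^4 + Kd^4) with n fixed at 4.

    ``surface`` is Gbg surface expression in arbitrary fluorescence units;
    ``currents`` the evoked GIRK currents (uA).  Only Imax and Kd are free.
    """
    g = np.asarray(surface, float)
    i = np.asarray(currents, float)
    if g.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(g < 0):
        raise ValueError("surface values must be >= 0")
    if np.all(i == 0):
        raise ValueError("all currents are zero; nothing to fit")

    def fn(x, imax, kd):
        return imax * x**4 / (x**4 + kd**4)

    pos = g[g > 0]
    p0 = [float(np.max(np.abs(i))), float(np.median(pos))]
    popt, pcov = curve_fit(
        fn, g, i, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        xtol=1e-12, ftol=1e-12,
    )
    rss = float(np.sum((fn(g, *popt) - i) ** 2))
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return ActivationFitParams(
        imax=float(popt[0]),
        kd=float(popt[1]),
        stderr={"imax": float(se[0]), "kd": float(se[1])},
        rss=rss,
    )
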