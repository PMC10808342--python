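"""Two-component mixture model for continuous-report recall errors.

Recall errors on the circle are modelled as a mixture of (1) a uniform
component capturing random guesses (failed retrieval), with weight ``p_u``,
and (2) a zero-mean von Mises component capturing noisy successful
retrieval, with weight ``p_t = 1 - p_u`` and concentration ``kappa``:

    p(e) = (1 - p_u) * vM(e; 0, kappa) + p_u / (2*pi)

Maximum-likelihood fits of (p_u, kappa) decompose performance into memory
success (p_t) and memory precision (kappa).  The fitted density also yields
a trial-level classifier: an error is attributed to successful retrieval
when it is more likely under the weighted von Mises component than under
the weighted uniform component, i.e. when |error| is below the crossover
angle where the two weighted densities are equal.

Numerical notes
---------------
* The von Mises density is evaluated through the exponentially scaled
  Bessel function ``i0e`` so that concentrations up to ~1e4 neither
  overflow nor lose precision.
* The likelihood is maximised over (logit(p_u), log(kappa)) with L-BFGS-B
  from a deterministic grid of starts, so fits are reproducible and robust
  to the bimodal likelihood that small samples can produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import optimize, special

from .angles import rad_to_deg, wrap_signed_deg

TWO_PI = 2.0 * np.pi

#: Raw-scale concentration bounds used by the optimiser.  The lower bound
#: keeps the von Mises component distinguishable from uniform; the upper
#: bound is far tighter than any plausible behavioural precision.
KAPPA_BOUNDS = (0.5, 500.0)

#: p_u is kept this far away from {0, 1} so the logit transform stays finite.
_PU_EPS = 1e-4

#: Deterministic multi-start grid (guess proportion x concentration).
_START_GRID = tuple(product((0.1, 0.5, 0.9), (2.0, 8.0, 32.0)))

#: Trial-level precision is 1/|error in deg|; errors below this floor are
#: clamped so a perfect response maps to the finite cap 1/_PRECISION_FLOOR_DEG.
_PRECISION_FLOOR_DEG = 0.5


def vonmises_density(x_rad, kappa: float):
    """Density of the zero-mean von Mises distribution at ``x_rad``.

    ``exp(kappa*cos x) / (2*pi*I0(kappa))``, computed stably for large
    ``kappa``.  ``kappa = 0`` gives the circular-uniform density 1/(2*pi).
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    x = np.asarray(x_rad, dtype=float)
    out = np.exp(kappa * (np.cos(x) - 1.0)) / (TWO_PI * special.i0e(kappa))
    return float(out) if out.ndim == 0 else out


def mixture_pdf(x_rad, p_u: float, kappa: float):
    """Mixture density (1-p_u)*vM(x; 0, kappa) + p_u/(2*pi)."""
    if not 0.0 <= p_u <= 1.0:
        raise ValueError(f"p_u must be in [0, 1], got {p_u}")
    return (1.0 - p_u) * vonmises_density(x_rad, kappa) + p_u / TWO_PI


def mixture_loglik(errors_rad, p_u: float, kappa: float) -> float:
    """Summed log mixture density of the errors, in nats.

    Densities are floored at the smallest positive normal float, so the
    result is always finite.
    """
    e = np.asarray(errors_rad, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    dens = mixture_pdf(e, p_u, kappa)
    return float(np.sum(np.log(np.maximum(dens, np.finfo(float).tiny))))


@dataclass(frozen=True)
class MixtureFit:
    """Maximum-likelihood estimate of the two-component mixture.

    ``p_t = 1 - p_u`` is memory success; ``kappa`` is memory precision.
    """

    p_u: float
    p_t: float
    kappa: float
    loglik: float
    n_trials: int
    converged: bool
    n_starts: int

    def to_dict(self) -> dict:
        return {
            "p_u": self.p_u,
            "p_t": self.p_t,
            "kappa": self.kappa,
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "n_starts": self.n_starts,
        }


def _neg_loglik_z(z: np.ndarray, errors_rad: np.ndarray) -> float:
    p_u = special.expit(z[0])
    kappa = np.exp(z[1])
    return -mixture_loglik(errors_rad, p_u, kappa)


def fit_mixture(
    errors_rad,
    kappa_bounds: tuple[float, float] = KAPPA_BOUNDS,
    extra_starts: tuple[tuple[float, float], ...] = (),
    min_trials: int = 10,
) -> MixtureFit:
    """Fit (p_u, kappa) by multi-start bounded maximum likelihood.

    Parameters
    ----------
    errors_rad
        Signed recall errors in radians (any real values; wrapped internally).
    kappa_bounds
        Raw-scale concentration bounds for the optimiser.
    extra_starts
        Additional (p_u, kappa) starting points appended to the built-in
        deterministic grid.
    min_trials
        Minimum number of errors required for a fit; fewer raises.
    """
    e = wrap_signed_deg(rad_to_deg(np.asarray(errors_rad, dtype=float)))
    e = np.deg2rad(e)
    if e.size < min_trials:
        raise ValueError(
            f"need at least {min_trials} trials to fit the mixture, got {e.size}"
        )
    lo_k, hi_k = kappa_bounds
    z_bounds = [
        (special.logit(_PU_EPS), special.logit(1.0 - _PU_EPS)),
        (np.log(lo_k), np.log(hi_k)),
    ]
    starts = list(_START_GRID) + list(extra_starts)

    best = None
    any_success = False
    for p0, k0 in starts:
        p0 = float(np.clip(p0, _PU_EPS, 1.0 - _PU_EPS))
        k0 = float(np.clip(k0, lo_k, hi_k))
        z0 = np.array([special.logit(p0), np.log(k0)])
        res = optimize.minimize(
            _neg_loglik_z,
            z0,
            args=(e,),
            method="L-BFGS-B",
            bounds=z_bounds,
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    p_u = float(special.expit(best.x[0]))
    kappa = float(np.exp(best.x[1]))
    fit = MixtureFit(
        p_u=p_u,
        p_t=1.0 - p_u,
        kappa=kappa,
        loglik=-float(best.fun),
        n_trials=int(e.size),
        converged=any_success,
        n_starts=len(starts),
    )
    if not any_success:
        warnings.warn("mixture fit did not converge from any start", RuntimeWarning)
    return fit


def crossover_threshold(p_u: float, kappa: float) -> float:
    """Angle (degrees, > 0) where the weighted components are equally likely.

    Solves ``(1 - p_u) * vM(x; kappa) = p_u / (2*pi)`` for x in (0, 180).
    Errors with |error| at or below the returned angle are more likely to
    come from successful retrieval than from guessing.

    Returns ``0.0`` if the uniform component dominates everywhere (including
    the degenerate p_u = 1), ``inf`` if the von Mises component dominates
    everywhere (including p_u = 0); degenerate inputs also warn.
    """
    if not np.isfinite(p_u) or not np.isfinite(kappa) or kappa < 0:
        raise ValueError(f"invalid mixture parameters p_u={p_u}, kappa={kappa}")
    if p_u <= 0.0:
        warnings.warn("degenerate fit p_u <= 0: every error classed correct")
        return np.inf
    if p_u >= 1.0:
        warnings.warn("degenerate fit p_u >= 1: every error classed incorrect")
        return 0.0

    # log density ratio of the weighted components; monotone in cos(x)
    def log_ratio(x):
        return (
            np.log1p(-p_u)
            + kappa * (np.cos(x) - 1.0)
            - np.log(special.i0e(kappa))
            - np.log(p_u)
        )

    if log_ratio(0.0) <= 0.0:
        return 0.0
    if log_ratio(np.pi) >= 0.0:
        return np.inf
    x_star = optimize.brentq(log_ratio, 0.0, np.pi, xtol=1e-12, rtol=1e-14)
    return float(rad_to_deg(x_star))


def threshold_from_fit(fit: MixtureFit) -> float:
    return crossover_threshold(fit.p_u, fit.kappa)


def classify_trials(errors_deg, threshold_deg: float):
    """Per-trial memory-success flags: correct iff |error| <= threshold.

    Ties at the crossover count as correct.
    """
    e = np.abs(wrap_signed_deg(errors_deg))
    return e <= threshold_deg


def trial_precision(errors_deg, correct=None, floor_deg: float = _PRECISION_FLOOR_DEG):
    """Trial-level precision: inverse absolute error (1/deg) on correct trials.

    Incorrect trials get NaN.  Absolute errors below ``floor_deg`` are
    clamped, so a zero-error response maps to the cap ``1/floor_deg``.
    """
    e = np.abs(wrap_signed_deg(errors_deg))
    prec = 1.0 / np.maximum(e, floor_deg)
    if correct is not None:
        prec = np.where(np.asarray(correct, bool), prec, np.nan)
    return prec
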