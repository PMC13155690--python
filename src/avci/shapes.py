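"""Prior distributions and sensory-noise functions of the observer models.

Two kinds of shape objects are provided:

* **Parametric families.**  Priors: a zero-mean Gaussian (``SingleGaussian``),
  a two-Gaussian mixture (``TwoGaussians``), and a Gaussian-Laplace mixture
  (``GaussianLaplace``), all centered at straight ahead (s = 0).  Noise
  functions: homoskedastic ``Const`` (sigma(s) = sigma0) and the saturating
  heteroskedastic ``Exp`` shape sigma(s) = sigma0 + k1 (1 - exp(-k2 |s|)).

* **Semiparametric pivot shapes.**  A shape is parameterized by its values at
  12 fixed pivot locations {0, 0.1, 0.3, 1, 2, 4, 6, 8, 10, 15, 20, 45}
  degrees, with monotone cubic interpolation in between and mirror symmetry
  about s = 0.  Noise shapes encode a base log-value plus 11 log-increments
  (cumulative sum of exponentials guarantees positivity and monotone growth
  with eccentricity); priors encode 11 log-decrements below a fixed
  log-density of 0 at the central pivot, exponentiated and normalized over the
  response range.

All priors are symmetric, non-negative, and normalized by the trapezoidal rule
over their support (default: the response range [-45, 45] degrees).  All noise
functions are positive, symmetric, and non-decreasing in |s|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

SUPPORT = (-45.0, 45.0)

#: Pivot locations (degrees) of the semiparametric shapes.
PIVOTS = np.array([0.0, 0.1, 0.3, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 45.0])

#: Lower bound on log-increments/log-decrements so "flat" shapes are representable.
LOG_INCREMENT_FLOOR = np.log(1e-6)

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class PivotGrid:
    """The fixed eccentricity grid at which semiparametric shapes are free."""

    locations: np.ndarray = field(default_factory=lambda: PIVOTS.copy())

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        if loc[0] != 0.0 or np.any(np.diff(loc) <= 0):
            raise ValueError("pivots must start at 0 and be strictly increasing")
        object.__setattr__(self, "locations", loc)

    def __len__(self) -> int:
        return len(self.locations)


@dataclass(frozen=True)
class ContextParams:
    """Context parameters shared by all observer models.

    alpha_med, alpha_low
        Multipliers on the visual noise function for medium/low reliability
        trials (high reliability is the baseline, multiplier 1).
    beta_V, beta_A
        Unisensory-to-bisensory noise multipliers, applied on bisensory trials
        only (attention diversion across modalities).
    rho_A
        Auditory range recalibration gain: the noisy auditory measurement is
        multiplied by rho_A immediately after generation and never corrected
        in later inference stages.  1 means no recalibration; 4/3 is a full
        remapping of the [-15, 15] auditory range onto the [-20, 20] visual
        range.
    p_same
        Prior probability that the two bisensory cues share a common source.
    lapse
        Probability of a uniform random response (localization) or fair
        category draw (causal judgment).
    sigma_motor
        SD (degrees) of the Gaussian motor noise on location reports.
    gamma
        Prior-shape exponent used by lifted semiparametric models (density
        proportional to p(s)**gamma, renormalized); 1 leaves the prior
        unchanged.
    """

    alpha_med: float = 1.0
    alpha_low: float = 1.0
    beta_V: float = 1.0
    beta_A: float = 1.0
    rho_A: float = 1.0
    p_same: float = 0.5
    lapse: float = 0.0
    sigma_motor: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_med", "alpha_low", "beta_V", "beta_A", "rho_A", "sigma_motor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_same", "lapse"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def reliability_multiplier(self, reliability: str | None) -> float:
        if reliability in (None, "high"):
            return 1.0
        if reliability == "med":
            return self.alpha_med
        if reliability == "low":
            return self.alpha_low
        raise ValueError(f"unknown reliability level {reliability!r}")


class NoiseModel:
    """Evaluable sensory-noise function sigma(s) for one modality."""

    def __init__(self, family: str, params: dict, modality: str = "V",
                 pivots: PivotGrid | None = None):
        if modality not in ("V", "A"):
            raise ValueError("modality must be 'V' or 'A'")
        self.family = family
        self.params = dict(params)
        self.modality = modality
        self.pivots = pivots or PivotGrid()
        if family == "Const":
            if self.params["sigma0"] <= 0:
                raise ValueError("sigma0 must be positive")
        elif family == "Exp":
            if self.params["sigma0"] <= 0 or self.params["k1"] < 0 or self.params["k2"] < 0:
                raise ValueError("Exp noise requires sigma0 > 0, k1 >= 0, k2 >= 0")
        elif family == "SemiparametricPivot":
            theta = np.asarray(self.params["theta"], dtype=float)
            if theta.shape != (len(self.pivots),):
                raise ValueError(
                    f"semiparametric noise needs {len(self.pivots)} log-values, got {theta.shape}"
                )
            values = np.cumsum(np.exp(theta))
            self._interp = PchipInterpolator(self.pivots.locations, values, extrapolate=False)
            self._pivot_values = values
        else:
            raise ValueError(f"unknown noise family {family!r}")

    def sigma(self, s):
        """Base noise SD (degrees) at stimulus location(s) s; symmetric in s."""
        a = np.abs(np.asarray(s, dtype=float))
        if self.family == "Const":
            out = np.full_like(a, self.params["sigma0"])
        elif self.family == "Exp":
            p = self.params
            out = p["sigma0"] + p["k1"] * (1.0 - np.exp(-p["k2"] * a))
        else:
            # constant extension beyond the outermost pivot
            out = self._interp(np.clip(a, 0.0, self.pivots.locations[-1]))
        return out if np.ndim(s) else float(out)

    __call__ = sigma


def noise_sigma(model: NoiseModel, s, reliability: str | None = None,
                context: ContextParams | None = None, bisensory: bool = False):
    """Effective noise SD: base shape scaled by reliability and bisensory factors.

    The reliability scaling (alpha_med / alpha_low) applies to vision only;
    passing a reliability level for an auditory noise model is an error.
    Bisensory trials additionally scale by beta_V or beta_A.
    """
    context = context or ContextParams()
    mult = 1.0
    if model.modality == "A":
        if reliability not in (None, "high") and reliability is not None:
            raise ValueError("reliability scaling applies to the visual modality only")
    else:
        mult *= context.reliability_multiplier(reliability)
    if bisensory:
        mult *= context.beta_V if model.modality == "V" else context.beta_A
    return model.sigma(s) * mult


class PriorModel:
    """Evaluable symmetric prior density over stimulus location.

    Parametric families are evaluated by closed form and renormalized over the
    bounded support so that all priors share one contract with the numerical
    engine (the truncated mass is negligible at fitted scales).
    """

    def __init__(self, family: str, params: dict, support: tuple = SUPPORT,
                 pivots: PivotGrid | None = None, base: "PriorModel | None" = None):
        self.family = family
        self.params = dict(params)
        self.support = tuple(support)
        self.pivots = pivots or PivotGrid()
        self.base = base
        self._norm_grid = self.make_norm_grid(self.support)
        if family == "SingleGaussian":
            if self.params["sigma_s"] <= 0:
                raise ValueError("sigma_s must be positive")
        elif family == "TwoGaussians":
            self._check_mixture(("sigma_s", "sigma_delta"))
        elif family == "GaussianLaplace":
            self._check_mixture(("sigma_s", "b"))
        elif family == "SemiparametricPivot":
            theta = np.asarray(self.params["theta"], dtype=float)
            if theta.shape != (len(self.pivots) - 1,):
                raise ValueError(
                    f"semiparametric prior needs {len(self.pivots) - 1} log-decrements, got {theta.shape}"
                )
            # log-density 0 at the central pivot, decreasing by exp(theta_j) per pivot
            logp = np.concatenate([[0.0], -np.cumsum(np.exp(theta))])
            self._interp = PchipInterpolator(self.pivots.locations, logp, extrapolate=False)
            self._pivot_logp = logp
        elif family == "Power":
            if base is None:
                raise ValueError("Power prior requires a base prior")
            if self.params["gamma"] < 0:
                raise ValueError("gamma must be non-negative")
        else:
            raise ValueError(f"unknown prior family {family!r}")
        self._Z = None

    @staticmethod
    def make_norm_grid(support: tuple = SUPPORT, refine: int = 1) -> np.ndarray:
        """Symmetric normalization grid, dense near s = 0.

        Laplace cusps and steep semiparametric log-slopes live near the
        center, so the grid uses 0.00025-degree steps on |s| <= 2 and
        0.00625-degree steps outside; ``refine`` halves the steps (used by
        tests to check the unit-mass invariant on an independent grid).
        """
        hi = support[1]
        zones = [(0.0, 0.5, 6.25e-5), (0.5, 2.0, 7.5e-4), (2.0, hi, 6.25e-3)]
        pieces = []
        for lo, up, h in zones:
            up = min(up, hi)
            if up <= lo:
                break
            n = int(np.ceil((up - lo) / h)) * refine + 1
            seg = np.linspace(lo, up, n)
            pieces.append(seg if not pieces else seg[1:])
        pos = np.concatenate(pieces)
        return np.concatenate([-pos[:0:-1], pos])

    def _check_mixture(self, scale_names: tuple) -> None:
        for name in scale_names:
            if self.params[name] <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.params["omega"] <= 1.0:
            raise ValueError("omega must lie in [0, 1]")

    def _unnormalized(self, s):
        a = np.asarray(s, dtype=float)
        p = self.params
        if self.family == "SingleGaussian":
            sig = p["sigma_s"]
            return np.exp(-0.5 * (a / sig) ** 2) / (sig * _SQRT2PI)
        if self.family == "TwoGaussians":
            s1, s2 = p["sigma_s"], p["sigma_s"] + p["sigma_delta"]
            g1 = np.exp(-0.5 * (a / s1) ** 2) / (s1 * _SQRT2PI)
            g2 = np.exp(-0.5 * (a / s2) ** 2) / (s2 * _SQRT2PI)
            return (1.0 - p["omega"]) * g1 + p["omega"] * g2
        if self.family == "GaussianLaplace":
            sig, b = p["sigma_s"], p["b"]
            g = np.exp(-0.5 * (a / sig) ** 2) / (sig * _SQRT2PI)
            lap = np.exp(-np.abs(a) / b) / (2.0 * b)
            return (1.0 - p["omega"]) * g + p["omega"] * lap
        if self.family == "SemiparametricPivot":
            aa = np.clip(np.abs(a), 0.0, self.pivots.locations[-1])
            return np.exp(self._interp(aa))
        # Power
        return self.base._unnormalized(a) ** p["gamma"]

    @property
    def norm(self) -> float:
        if self._Z is None:
            self._Z = float(np.trapezoid(self._unnormalized(self._norm_grid), self._norm_grid))
            if not np.isfinite(self._Z) or self._Z <= 0:
                raise ValueError("prior density is not normalizable on its support")
        return self._Z

    def pdf(self, s):
        """Normalized density (1/deg) at s; zero outside the support."""
        a = np.asarray(s, dtype=float)
        out = self._unnormalized(a) / self.norm
        out = np.where((a < self.support[0]) | (a > self.support[1]), 0.0, out)
        return out if np.ndim(s) else float(out)

    __call__ = pdf


def build_semiparametric_noise(theta, pivots: PivotGrid | None = None,
                               modality: str = "V") -> NoiseModel:
    """Noise shape from 12 log-values: sigma(0) = exp(theta_0), then cumulative
    exp(theta_j) increments at successive pivots, monotone-cubic interpolated."""
    theta = np.asarray(theta, dtype=float)
    pivots = pivots or PivotGrid()
    if theta.shape != (len(pivots),):
        raise ValueError(f"expected {len(pivots)} log-values, got {theta.shape}")
    return NoiseModel("SemiparametricPivot", {"theta": theta}, modality=modality, pivots=pivots)


def build_semiparametric_prior(theta, pivots: PivotGrid | None = None,
                               support: tuple = SUPPORT) -> PriorModel:
    """Prior shape from 11 log-decrements of the log-density below the central
    pivot (whose log-density is fixed to 0 before normalization)."""
    theta = np.asarray(theta, dtype=float)
    pivots = pivots or PivotGrid()
    if theta.shape != (len(pivots) - 1,):
        raise ValueError(f"expected {len(pivots) - 1} log-decrements, got {theta.shape}")
    return PriorModel("SemiparametricPivot", {"theta": theta}, support=support, pivots=pivots)


def apply_recalibration(x_A, rho_A: float):
    """Auditory range recalibration: scale the noisy auditory measurement.

    The scaled value feeds all downstream inference unchanged (the observer
    does not correct for the recalibration).
    """
    return np.asarray(x_A, dtype=float) * rho_A if np.ndim(x_A) else float(x_A) * rho_A


def apply_prior_exponent(prior: PriorModel, gamma: float) -> PriorModel:
    """Prior sharpening/flattening: density proportional to p(s)**gamma."""
    if gamma == 1.0:
        return prior
    return PriorModel("Power", {"gamma": gamma}, support=prior.support, base=prior)


def flat_noise_theta(level: float, pivots: PivotGrid | None = None) -> np.ndarray:
    """Semiparametric log-values of an (effectively) flat noise shape at ``level`` deg."""
    pivots = pivots or PivotGrid()
    theta = np.full(len(pivots), LOG_INCREMENT_FLOOR)
    theta[0] = np.log(level)
    return theta


def flat_prior_theta(pivots: PivotGrid | None = None) -> np.ndarray:
    """Semiparametric log-decrements of an (effectively) uniform prior."""
    pivots = pivots or PivotGrid()
    return np.full(len(pivots) - 1, LOG_INCREMENT_FLOOR)
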