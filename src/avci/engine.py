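"""Numerical likelihood engine for the five observer tasks.

Computes exact-model response probabilities by trapezoidal quadrature:

* UV/UA: p(r | s) — the posterior-mean estimate shat(x) is integrated over the
  Gaussian measurement distribution of x, then convolved with motor noise and
  mixed with the uniform lapse component.
* BC: p(rC = 1 | sV, sA) — the common-cause posterior p(C=1 | xV, xA) is
  integrated over both measurement distributions, either as an indicator of
  p > 0.5 (Model Selection / Model Averaging, equivalent for this task) or
  weighted by the posterior itself (Probability Matching).
* BV/BA: p(r | sV, sA) — the fused (C=1) and single-cue (C=2) posterior-mean
  estimates are combined per the causal strategy (MS picks the more probable
  hypothesis's estimate, MA takes the posterior-weighted average, PM mixes the
  two motor-noise Gaussians by posterior weight), integrated over both
  measurement distributions.

Auditory recalibration is applied once, in the measurement layer: the
generative measurement is x_A ~ N(s_A, sigma_A^2(s_A)) and every inference
formula sees m_A = rho_A * x_A with the unmodified noise model.  The observer's
believed noise equals the true noise, including the reliability (alpha) and
bisensory (beta) multipliers.

Efficiency notes: the unisensory posterior mean shat(x) and the bisensory
quantities p(C=1 | mV, mA), fused mean, and single-cue means are precomputed on
shared measurement grids per reliability level and interpolated at the
per-trial measurement nodes (center +/- 5 sigma Gaussian quadrature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from avci.shapes import (
    ContextParams,
    NoiseModel,
    PriorModel,
    apply_prior_exponent,
    noise_sigma,
)

STRATEGIES = ("MS", "MA", "PM")
_WARNED_DEGENERATE = False
HALF_RANGE = 45.0
RANGE_WIDTH = 90.0
_SQRT2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x, mu, sigma):
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * _SQRT2PI)


def _trap_weights(grid: np.ndarray) -> np.ndarray:
    h = grid[1] - grid[0]
    w = np.full(grid.shape, h)
    w[0] = w[-1] = 0.5 * h
    return w


@dataclass(frozen=True)
class GridSpec:
    """Numerical grids of the engine.

    s_points
        Points of the hypothesis grid on [-45, 45] (721 -> 0.125 deg spacing);
        must resolve the smallest plausible sigma(s).
    n_x
        Per-trial measurement nodes, spanning center +/- k_sigma * sigma.
    x_table_step / x_table_half
        Spacing and half-range of the shared measurement grid on which
        shat(x) (unisensory) is tabulated.
    m_table_step / m_table_half
        Spacing and half-range of the shared 2-D internal-measurement grids of
        the bisensory tables.
    n_x_bisensory
        Per-trial measurement nodes per modality on bisensory trials.
    """

    s_points: int = 721
    n_x: int = 201
    k_sigma: float = 5.0
    x_table_step: float = 0.25
    x_table_half: float = 90.0
    m_table_step: float = 0.5
    m_table_half: float = 90.0
    n_x_bisensory: int = 61
    n_x_bc: int = 161

    @property
    def s_grid(self) -> np.ndarray:
        return np.linspace(-HALF_RANGE, HALF_RANGE, self.s_points)

    @property
    def x_table(self) -> np.ndarray:
        n = int(round(2 * self.x_table_half / self.x_table_step)) + 1
        return np.linspace(-self.x_table_half, self.x_table_half, n)

    @property
    def m_table(self) -> np.ndarray:
        n = int(round(2 * self.m_table_half / self.m_table_step)) + 1
        return np.linspace(-self.m_table_half, self.m_table_half, n)

    def halved(self) -> "GridSpec":
        """A grid twice as fine in every dimension (for convergence checks)."""
        return replace(
            self,
            s_points=2 * self.s_points - 1,
            n_x=2 * self.n_x - 1,
            x_table_step=self.x_table_step / 2,
            m_table_step=self.m_table_step / 2,
            n_x_bisensory=2 * self.n_x_bisensory - 1,
            n_x_bc=2 * self.n_x_bc - 1,
        )


@dataclass
class ObserverModel:
    """A full observer specification: prior, per-modality noise, causal
    strategy, context parameters, and numerical grids."""

    prior: PriorModel
    noise_V: NoiseModel
    noise_A: NoiseModel
    strategy: str = "PM"
    context: ContextParams = field(default_factory=ContextParams)
    grids: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.context.gamma != 1.0:
            self.prior = apply_prior_exponent(self.prior, self.context.gamma)
            self.context = replace(self.context, gamma=1.0)
        self._uni_cache: dict = {}
        self._bi_cache: dict = {}

    # ---------------- generative / effective noise ----------------

    def sigma_eff(self, s, modality: str, reliability: str | None, bisensory: bool):
        noise = self.noise_V if modality == "V" else self.noise_A
        rel = reliability if modality == "V" else None
        return noise_sigma(noise, s, rel, self.context, bisensory)

    # ---------------- unisensory ----------------

    def _shat_table(self, modality: str, reliability: str | None, bisensory: bool):
        """Posterior-mean estimate shat(m) tabulated on the shared measurement grid."""
        key = (modality, reliability, bisensory)
        if key not in self._uni_cache:
            s = self.grids.s_grid
            sig = np.maximum(self.sigma_eff(s, modality, reliability, bisensory), 1e-12)
            wp = _trap_weights(s) * self.prior.pdf(s)
            m = self.grids.x_table
            like = _norm_pdf(m[None, :], s[:, None], sig[:, None])
            num = (s * wp) @ like
            den = wp @ like
            bad = den <= 0.0
            if np.any(bad):
                global _WARNED_DEGENERATE
                if not _WARNED_DEGENERATE:
                    _WARNED_DEGENERATE = True
                    warnings.warn(
                        "degenerate posterior (zero mass) at extreme measurements; "
                        "falling back to the clipped measurement (reported once)",
                        RuntimeWarning,
                    )
                den = np.where(bad, 1.0, den)
                num = np.where(bad, np.clip(m, -HALF_RANGE, HALF_RANGE), num)
            self._uni_cache[key] = (m, num / den)
        return self._uni_cache[key]

    def posterior_mean_unisensory(self, x, modality: str, reliability: str | None = None,
                                  bisensory: bool = False):
        """Exact posterior-mean estimate at internal measurement(s) x.

        For audition, x must already be recalibrated (m_A = rho_A * x_A).
        Direct quadrature over the hypothesis grid; used by tests and the
        simulator, independent of the tabulated path.
        """
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        s = self.grids.s_grid
        sig = np.maximum(self.sigma_eff(s, modality, reliability, bisensory), 1e-12)
        wp = _trap_weights(s) * self.prior.pdf(s)
        like = _norm_pdf(xa[:, None], s[None, :], sig[None, :])
        den = like @ wp
        if np.any(den <= 0.0):
            raise FloatingPointError("degenerate posterior: zero mass at measurement")
        out = (like @ (s * wp)) / den
        return out if np.ndim(x) else float(out[0])

    def _x_nodes(self):
        u = np.linspace(-self.grids.k_sigma, self.grids.k_sigma, self.grids.n_x)
        w = _trap_weights(u) * np.exp(-0.5 * u * u) / _SQRT2PI
        return u, w / w.sum()  # renormalize the +/- k_sigma truncation

    def unisensory_response_density(self, s, reliability, task: str, r):
        """p(r | s) for UV or UA, vectorized over trials (s, r aligned arrays)."""
        if task not in ("UV", "UA"):
            raise ValueError("task must be UV or UA")
        modality = "V" if task == "UV" else "A"
        if task == "UA" and reliability is not None:
            raise ValueError("UA trials carry no visual reliability level")
        s = np.atleast_1d(np.asarray(s, dtype=float))
        r = np.atleast_1d(np.asarray(r, dtype=float))
        ctx = self.context
        sig_gen = self.sigma_eff(s, modality, reliability, False)
        u, w = self._x_nodes()
        x = s[:, None] + sig_gen[:, None] * u[None, :]
        m = ctx.rho_A * x if modality == "A" else x
        mt, shat_t = self._shat_table(modality, reliability, False)
        shat = np.interp(m, mt, shat_t)
        dens = _norm_pdf(r[:, None], shat, ctx.sigma_motor) @ w
        out = (1.0 - ctx.lapse) * dens + ctx.lapse / RANGE_WIDTH
        out = np.where(np.abs(r) <= HALF_RANGE, out, (1.0 - ctx.lapse) * dens)
        return out

    def unisensory_density_grid(self, s: float, reliability, task: str,
                                r_grid: np.ndarray) -> np.ndarray:
        """p(r | s) for one stimulus on a response grid (for summaries/plots)."""
        s_rep = np.full(len(r_grid), float(s))
        return self.unisensory_response_density(s_rep, reliability, task, r_grid)

    # ---------------- bisensory tables ----------------

    def _bi_tables(self, reliability: str):
        """Shared-grid tables on internal measurement axes (mV, mA).

        Returns (mV_grid, mA_grid, P1, fused_mean, shat_V(mV), shat_A(mA)).
        The auditory axis is rho_A times the base grid, so per-trial
        recalibrated measurements stay inside the table under sane parameters.
        """
        if reliability not in self._bi_cache:
            ctx = self.context
            s = self.grids.s_grid
            wp = _trap_weights(s) * self.prior.pdf(s)
            mV = self.grids.m_table
            mA = ctx.rho_A * self.grids.m_table
            sigV = np.maximum(self.sigma_eff(s, "V", reliability, True), 1e-12)
            sigA = np.maximum(self.sigma_eff(s, "A", None, True), 1e-12)
            A = _norm_pdf(mV[None, :], s[:, None], sigV[:, None])  # (n_s, n_mV)
            B = _norm_pdf(mA[None, :], s[:, None], sigA[:, None])  # (n_s, n_mA)
            Awp = A * wp[:, None]
            L1 = Awp.T @ B                       # common-cause evidence
            F_num = (A * (s * wp)[:, None]).T @ B
            LV = wp @ A
            LA = wp @ B
            sV_num = (s * wp) @ A
            sA_num = (s * wp) @ B
            tiny = 1e-300
            evid = ctx.p_same * L1 + (1.0 - ctx.p_same) * (LV[:, None] * LA[None, :])
            P1 = ctx.p_same * L1 / np.maximum(evid, tiny)
            fused = F_num / np.maximum(L1, tiny)
            shat_V = sV_num / np.maximum(LV, tiny)
            shat_A = sA_num / np.maximum(LA, tiny)
            self._bi_cache[reliability] = (mV, mA, P1, fused, shat_V, shat_A)
        return self._bi_cache[reliability]

    def causal_posterior(self, x_V, x_A):
        """Exact p(C=1 | xV, xA) at internal measurements, by direct quadrature.

        x_A must already be recalibrated.  Vectorized over aligned arrays;
        bisensory beta-scaled noise is in force.  The reliability level of the
        trial enters through :meth:`causal_posterior_at`; this method uses the
        high-reliability visual noise.
        """
        return self.causal_posterior_at(x_V, x_A, "high")

    def causal_posterior_at(self, x_V, x_A, reliability: str):
        xv = np.atleast_1d(np.asarray(x_V, dtype=float))
        xa = np.atleast_1d(np.asarray(x_A, dtype=float))
        ctx = self.context
        s = self.grids.s_grid
        wp = _trap_weights(s) * self.prior.pdf(s)
        sigV = np.maximum(self.sigma_eff(s, "V", reliability, True), 1e-12)
        sigA = np.maximum(self.sigma_eff(s, "A", None, True), 1e-12)
        likV = _norm_pdf(xv[:, None], s[None, :], sigV[None, :])
        likA = _norm_pdf(xa[:, None], s[None, :], sigA[None, :])
        L1 = (likV * likA) @ wp
        LV = likV @ wp
        LA = likA @ wp
        evid = ctx.p_same * L1 + (1.0 - ctx.p_same) * LV * LA
        if np.any(evid <= 0.0):
            raise FloatingPointError("zero total evidence in causal posterior")
        out = ctx.p_same * L1 / evid
        return out if np.ndim(x_V) else float(out[0])

    def posterior_means_bisensory(self, x_V, x_A, target: str, reliability: str = "high"):
        """(shat_C1, shat_C2) at internal measurements, by direct quadrature.

        shat_C1 is the fused common-cause posterior mean; shat_C2 is the
        single-cue posterior mean of the target modality (independent of the
        other measurement).
        """
        xv = np.atleast_1d(np.asarray(x_V, dtype=float))
        xa = np.atleast_1d(np.asarray(x_A, dtype=float))
        ctx = self.context
        s = self.grids.s_grid
        wp = _trap_weights(s) * self.prior.pdf(s)
        sigV = np.maximum(self.sigma_eff(s, "V", reliability, True), 1e-12)
        sigA = np.maximum(self.sigma_eff(s, "A", None, True), 1e-12)
        likV = _norm_pdf(xv[:, None], s[None, :], sigV[None, :])
        likA = _norm_pdf(xa[:, None], s[None, :], sigA[None, :])
        joint = likV * likA
        fused = (joint @ (s * wp)) / np.maximum(joint @ wp, 1e-300)
        lik_t = likV if target == "V" else likA
        single = (lik_t @ (s * wp)) / np.maximum(lik_t @ wp, 1e-300)
        if np.ndim(x_V):
            return fused, single
        return float(fused[0]), float(single[0])

    # ---------------- bisensory likelihoods ----------------

    def _bi_nodes(self, s_V, s_A, reliability, n_nodes=None):
        """Per-trial generative measurement nodes and shared Gaussian weights.

        The causal-judgment (BC) path uses a denser node set: its MS/MA
        integrand is an indicator, whose trapezoid error decays only linearly
        in the node spacing.
        """
        g = self.grids
        u = np.linspace(-g.k_sigma, g.k_sigma, n_nodes or g.n_x_bisensory)
        w = _trap_weights(u) * np.exp(-0.5 * u * u) / _SQRT2PI
        w = w / w.sum()
        sigV = self.sigma_eff(s_V, "V", reliability, True)
        sigA = self.sigma_eff(s_A, "A", None, True)
        xV = s_V[:, None] + sigV[:, None] * u[None, :]
        xA = s_A[:, None] + sigA[:, None] * u[None, :]
        return xV, xA, w

    @staticmethod
    def _interp1(grid, values, q):
        return np.interp(q, grid, values)

    @staticmethod
    def _bilinear(gx, gy, table, qx, qy):
        """Bilinear interpolation of table (len(gx), len(gy)) at the product
        nodes qx (n, kx) x qy (n, ky) -> (n, kx, ky)."""
        hx = gx[1] - gx[0]
        hy = gy[1] - gy[0]
        ix = np.clip(((qx - gx[0]) / hx).astype(int), 0, len(gx) - 2)
        iy = np.clip(((qy - gy[0]) / hy).astype(int), 0, len(gy) - 2)
        fx = np.clip((qx - gx[ix]) / hx, 0.0, 1.0)
        fy = np.clip((qy - gy[iy]) / hy, 0.0, 1.0)
        ix_ = ix[:, :, None]
        iy_ = iy[:, None, :]
        fx_ = fx[:, :, None]
        fy_ = fy[:, None, :]
        t00 = table[ix_, iy_]
        t10 = table[ix_ + 1, iy_]
        t01 = table[ix_, iy_ + 1]
        t11 = table[ix_ + 1, iy_ + 1]
        return (t00 * (1 - fx_) * (1 - fy_) + t10 * fx_ * (1 - fy_)
                + t01 * (1 - fx_) * fy_ + t11 * fx_ * fy_)

    def bc_response_probability(self, s_V, s_A, reliability):
        """p(rC = 1 | sV, sA) including the lapse mixture, per trial."""
        s_V = np.atleast_1d(np.asarray(s_V, dtype=float))
        s_A = np.atleast_1d(np.asarray(s_A, dtype=float))
        ctx = self.context
        mVg, mAg, P1, _, _, _ = self._bi_tables(reliability)
        out = np.empty(len(s_V))
        for lo in range(0, len(s_V), 64):
            sl = slice(lo, lo + 64)
            xV, xA, w = self._bi_nodes(s_V[sl], s_A[sl], reliability,
                                       n_nodes=self.grids.n_x_bc)
            p1 = self._bilinear(mVg, mAg, P1, xV, ctx.rho_A * xA)
            if self.strategy in ("MS", "MA"):
                # ties at exactly 0.5 count as C = 1, for determinism
                p1 = (p1 >= 0.5).astype(float)
            out[sl] = np.einsum("i,nij,j->n", w, p1, w)
        return ctx.lapse / 2.0 + (1.0 - ctx.lapse) * out

    def bisensory_localization_density(self, s_V, s_A, reliability, target: str, r):
        """p(r | sV, sA) for BV (target 'V') or BA (target 'A'), per trial."""
        if target not in ("V", "A"):
            raise ValueError("target must be 'V' or 'A'")
        s_V = np.atleast_1d(np.asarray(s_V, dtype=float))
        s_A = np.atleast_1d(np.asarray(s_A, dtype=float))
        r = np.atleast_1d(np.asarray(r, dtype=float))
        ctx = self.context
        mVg, mAg, P1, fused, shat_V, shat_A = self._bi_tables(reliability)
        dens = np.empty(len(s_V))
        for lo in range(0, len(s_V), 256):
            sl = slice(lo, lo + 256)
            xV, xA, w = self._bi_nodes(s_V[sl], s_A[sl], reliability)
            mA = ctx.rho_A * xA
            p1 = self._bilinear(mVg, mAg, P1, xV, mA)
            f = self._bilinear(mVg, mAg, fused, xV, mA)
            if target == "V":
                s2 = self._interp1(mVg, shat_V, xV)[:, :, None]
            else:
                s2 = self._interp1(mAg, shat_A, mA)[:, None, :]
            rr = r[sl][:, None, None]
            if self.strategy == "MS":
                est = np.where(p1 >= 0.5, f, s2)
                q = _norm_pdf(rr, est, ctx.sigma_motor)
            elif self.strategy == "MA":
                est = p1 * f + (1.0 - p1) * s2
                q = _norm_pdf(rr, est, ctx.sigma_motor)
            else:  # PM: mixture of the two hypothesis estimates
                q = (p1 * _norm_pdf(rr, f, ctx.sigma_motor)
                     + (1.0 - p1) * _norm_pdf(rr, s2 * np.ones_like(p1), ctx.sigma_motor))
            dens[sl] = np.einsum("i,nij,j->n", w, q, w)
        out = (1.0 - ctx.lapse) * dens + ctx.lapse / RANGE_WIDTH
        return np.where(np.abs(r) <= HALF_RANGE, out, (1.0 - ctx.lapse) * dens)

    # ---------------- per-trial likelihood dispatch ----------------

    def trial_likelihoods(self, table) -> np.ndarray:
        """Per-trial response probability/density for a responded trial table.

        Localization trials yield densities (1/deg), BC trials probabilities.
        Rows are returned in the input order.
        """
        out = np.empty(len(table))
        task = table["task"].to_numpy()
        rel = table["reliability"].to_numpy(dtype=object)
        sV = table["s_V"].to_numpy(dtype=float)
        sA = table["s_A"].to_numpy(dtype=float)
        r_loc = table["response_loc"].to_numpy(dtype=float)
        r_cat = table["response_cat"].to_numpy(dtype=float)
        for level in (None, "high", "med", "low"):
            if level is None:
                idx = np.flatnonzero(task == "UA")
                if idx.size:
                    out[idx] = self.unisensory_response_density(
                        sA[idx], None, "UA", r_loc[idx])
                continue
            sel = rel == level
            idx = np.flatnonzero(sel & (task == "UV"))
            if idx.size:
                out[idx] = self.unisensory_response_density(
                    sV[idx], level, "UV", r_loc[idx])
            idx = np.flatnonzero(sel & (task == "BC"))
            if idx.size:
                p1 = self.bc_response_probability(sV[idx], sA[idx], level)
                out[idx] = np.where(r_cat[idx] == 1, p1, 1.0 - p1)
            for target, tname in (("V", "BV"), ("A", "BA")):
                idx = np.flatnonzero(sel & (task == tname))
                if idx.size:
                    out[idx] = self.bisensory_localization_density(
                        sV[idx], sA[idx], level, target, r_loc[idx])
        return out
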