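"""Mean-field kinetic simulation of synaptic vesicle pools under stain/destain protocols.

The simulator represents one presynaptic terminal as a small set of vesicle
pools.  In the *parallel* organization each path couples a readily releasable
pool (RRP) subdivision to its own reserve pool: path 0 is the fast-releasing /
quickly mobilized path, path 1 the reluctant / slowly mobilized path.  The
*serial* organization chains a deep reserve behind the quickly mobilized
reserve of a single release path, and the *lifo* organization stores a single
reserve as an ordered stack in which the most recently recycled vesicles are
mobilized first.

Bookkeeping is per dye channel: every pool tracks its total vesicle count and
the number of vesicles labeled with each of two FM dyes.  Exocytosis of a
stained vesicle destains it completely; the vesicle membrane is recycled
immediately and re-enters a reserve pool, picking up whichever dye is in the
bath at that moment.  Total vesicle number is therefore conserved by every
pulse; only labels move.

Two regimes matter.  At low stimulation frequency the RRP is refilled between
pulses and destaining is limited by release probability; at high frequency
the RRP is driven to a near-empty steady state and destaining is limited by
recruitment of reserve vesicles, whose timing is shared between paths.  The
per-action-potential release probability is therefore regime dependent (see
``ModelSpec.p_release_hf``).

Spontaneous exchange between a path's RRP and its reserve is fast (order one
minute) compared to destaining, and is idealized here as instantaneous label
homogenization within each path; the LIFO topology, whose whole point is the
absence of such mixing, is exempt.

Units: the simulator works in seconds; destaining rates at the analysis
interface are in min^-1 and the conversion is always explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "VesicleState",
    "SimTrace",
    "SimResult",
    "closed_form_biexp",
    "apply_pulse",
    "evolve_rest",
    "simulate",
    "initial_state",
    "default_parallel",
    "default_serial",
    "default_lifo",
    "single_pool",
    "rate_to_pulse_prob",
    "pulse_prob_to_rate",
]

# Calibrated default biexponential decomposition of 1 Hz destaining:
# weight of the fast component and per-path fractional destaining rates
# (min^-1) chosen so that the windowed fractional-destaining estimator on the
# noiseless trace reproduces 0.087 min^-1 on minutes [0, 1.5) and
# 0.032 min^-1 on minutes [21, 25).  fmpools.synthetic.calibrate recomputes
# these at run time; a test pins the agreement.
W_FAST_DEFAULT = 0.39
K_FAST_1HZ = 0.200830634128  # min^-1, quickly mobilized path at 1 Hz
K_SLOW_1HZ = 0.031925999368  # min^-1, slowly mobilized path at 1 Hz

RRP_TOTAL_DEFAULT = 6.0  # vesicles per terminal (readily releasable, 5-7)
RESERVE_TOTAL_DEFAULT = 40.0  # vesicles per terminal (reserve, 35-50)
RECRUIT_RATE_DEFAULT = 1.0 / 28.0  # s^-1; 20 Hz destaining then has tau ~ 28 s

# Per-AP, per-RRP-vesicle release probabilities in the high-frequency regime,
# where exocytosis runs at its maximal rate: fast sites empty their RRP
# subdivision with tau ~ 0.3 s of 20 Hz, reluctant sites with tau ~ 0.6 s.
P_RELEASE_HF_DEFAULT = (0.15, 0.08)
HF_THRESHOLD_DEFAULT = 10.0  # Hz; boundary between the two regimes

_CHANNELS = ("dye1", "dye2")


def rate_to_pulse_prob(k_per_min: float, frequency_hz: float) -> float:
    """Exact per-pulse fractional loss equivalent to a continuous rate.

    A pool destaining at ``k_per_min`` sampled at ``frequency_hz`` pulses per
    second loses the fraction ``1 - exp(-k/(60 f))`` per pulse.
    """
    return -np.expm1(-k_per_min / (60.0 * frequency_hz))


def pulse_prob_to_rate(q: float, frequency_hz: float) -> float:
    """Inverse of :func:`rate_to_pulse_prob` (min^-1)."""
    return -60.0 * frequency_hz * np.log1p(-q)


def closed_form_biexp(w: float, kf: float, ks: float, t) -> np.ndarray:
    """Weighted sum of two exponentials, ``w e^(-kf t) + (1-w) e^(-ks t)``.

    ``t`` is in minutes when the rates are in min^-1.  This is the closed form
    a parallel two-path model destains along at constant low frequency.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight w={w} outside [0, 1]")
    if not kf >= ks >= 0.0:
        raise ValueError(f"rates must satisfy kf >= ks >= 0, got {kf}, {ks}")
    t = np.asarray(t, dtype=float)
    return w * np.exp(-kf * t) + (1.0 - w) * np.exp(-ks * t)


@dataclass(frozen=True)
class ModelSpec:
    """Topology, sizes, and rate constants of a simulated terminal.

    Parameters
    ----------
    topology:
        ``"parallel"`` (independent fast and reluctant paths), ``"serial"``
        (deep reserve chained behind a quickly mobilized reserve), or
        ``"lifo"`` (single reserve stored as a last-in/first-out stack).
    rrp_size_per_path, reserve_size_per_path:
        Resting vesicle counts per path.  For ``serial`` the second entry is
        the deep reserve (its RRP entry must be 0); for ``lifo`` one path.
    p_release, p_release_hf:
        Per-AP release probability of each readily releasable vesicle in the
        low- and high-frequency regimes (boundary ``hf_threshold_hz``).
    recruit_rate:
        First-order rate (s^-1) at which reserve vesicles are recruited to
        vacant RRP space; shared across paths, so recruitment timing is the
        same for fast and reluctant subdivisions.
    maturation_rate:
        Serial topology only: first-order rate (s^-1) of transfer from the
        deep reserve into the quickly mobilized reserve.
    mixing_rate:
        First-order relaxation rate (s^-1) of the two reserves' labeled
        fractions toward their common pooled value (0 = no intermixing).
        With ``mixing_active_above_hz`` set, mixing operates only while
        stimulating at or above that frequency (activity-dependent mixing);
        for the LIFO topology it homogenizes the stack.
    recycle_rule:
        Where recycled vesicle membrane re-enters the reserves.
        ``"quick_first"`` (default): during low-frequency stimulation the
        recycled vesicle joins the quickly mobilized reserve and the inflow
        excess displaces quick-reserve-composition vesicles into the slow
        reserve (pool sizes conserved); during high-frequency stimulation
        vesicles return to their source path.  ``"return_to_source_path"``
        and ``"proportional_split"`` are frequency independent.
    baseline_loss_rate:
        Fractional loss of labeled content, %/min-style rate given per
        *minute* (e.g. 0.0158 for 1.58 %/min), applied to all stained pools.
    stochastic:
        If True, per-pulse release counts are binomial draws (pass an ``rng``
        to the drivers); default is deterministic mean-field.
    """

    topology: str = "parallel"
    n_paths: int = 2
    rrp_size_per_path: tuple[float, ...] = (
        W_FAST_DEFAULT * RRP_TOTAL_DEFAULT,
        (1 - W_FAST_DEFAULT) * RRP_TOTAL_DEFAULT,
    )
    reserve_size_per_path: tuple[float, ...] = (
        W_FAST_DEFAULT * RESERVE_TOTAL_DEFAULT,
        (1 - W_FAST_DEFAULT) * RESERVE_TOTAL_DEFAULT,
    )
    p_release: tuple[float, ...] = (
        # per-AP probabilities reproducing the calibrated 1 Hz path rates:
        # p = (1 - e^(-k/60)) * N/R with N/R identical for both paths
        rate_to_pulse_prob(K_FAST_1HZ, 1.0)
        * (RRP_TOTAL_DEFAULT + RESERVE_TOTAL_DEFAULT) / RRP_TOTAL_DEFAULT,
        rate_to_pulse_prob(K_SLOW_1HZ, 1.0)
        * (RRP_TOTAL_DEFAULT + RESERVE_TOTAL_DEFAULT) / RRP_TOTAL_DEFAULT,
    )
    p_release_hf: tuple[float, ...] = P_RELEASE_HF_DEFAULT
    hf_threshold_hz: float = HF_THRESHOLD_DEFAULT
    recruit_rate: float = RECRUIT_RATE_DEFAULT
    maturation_rate: float = 0.0
    mixing_rate: float = 0.0
    mixing_active_above_hz: float | None = None
    recycle_rule: str = "quick_first"
    baseline_loss_rate: float = 0.0
    stochastic: bool = False

    def __post_init__(self):
        if self.topology not in ("parallel", "serial", "lifo"):
            raise ValueError(f"unknown topology {self.topology!r}")
        n = self.n_paths
        for name in ("rrp_size_per_path", "reserve_size_per_path",
                     "p_release", "p_release_hf"):
            v = getattr(self, name)
            if np.isscalar(v):
                v = (float(v),) * n
            v = tuple(float(x) for x in v)
            if len(v) != n:
                raise ValueError(f"{name} must have {n} entries, got {v}")
            object.__setattr__(self, name, v)
        if any(p < 0 or p > 1 for p in self.p_release + self.p_release_hf):
            raise ValueError("release probabilities must lie in [0, 1]")
        for r in (self.recruit_rate, self.maturation_rate, self.mixing_rate,
                  self.baseline_loss_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.topology == "serial":
            if self.n_paths != 2 or self.rrp_size_per_path[1] != 0.0:
                raise ValueError(
                    "serial topology uses 2 compartments with "
                    "rrp_size_per_path=(rrp, 0) — the deep reserve has no RRP")
        if any(s <= 0 for s in self.reserve_size_per_path) or \
                self.rrp_size_per_path[0] <= 0:
            raise ValueError("pool sizes must be positive")
        if self.recycle_rule not in (
                "quick_first", "return_to_source_path", "proportional_split"):
            raise ValueError(f"unknown recycle_rule {self.recycle_rule!r}")

    # -- convenience -------------------------------------------------------
    def p_for_frequency(self, frequency_hz: float | None) -> np.ndarray:
        """Per-path release probabilities applicable at a given frequency."""
        if frequency_hz is not None and frequency_hz >= self.hf_threshold_hz:
            return np.asarray(self.p_release_hf)
        return np.asarray(self.p_release)

    def mixing_active(self, frequency_hz: float | None) -> bool:
        if self.mixing_rate == 0.0:
            return False
        if self.mixing_active_above_hz is None:
            return True
        return frequency_hz is not None and \
            frequency_hz >= self.mixing_active_above_hz

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        for k in ("rrp_size_per_path", "reserve_size_per_path",
                  "p_release", "p_release_hf"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def _p_from_path_rate(k_per_min: float, rrp: float, reserve: float) -> float:
    # Path fractional destaining kappa per pulse at 1 Hz equals
    # p * R / N when the RRP is refilled between pulses and labels are
    # homogeneous within the path; invert for p.
    n = rrp + reserve
    return rate_to_pulse_prob(k_per_min, 1.0) * n / rrp


def default_parallel(
    w_fast: float = W_FAST_DEFAULT,
    k_fast: float = K_FAST_1HZ,
    k_slow: float = K_SLOW_1HZ,
    rrp_total: float = RRP_TOTAL_DEFAULT,
    reserve_total: float = RESERVE_TOTAL_DEFAULT,
    **overrides,
) -> ModelSpec:
    """Calibrated two-path parallel model.

    Pool sizes split ``w_fast`` / ``1 - w_fast`` between the fast and
    reluctant paths; per-AP release probabilities are chosen so the path
    fractional destaining rates at 1 Hz equal ``k_fast`` and ``k_slow``.
    """
    rrp = (w_fast * rrp_total, (1 - w_fast) * rrp_total)
    res = (w_fast * reserve_total, (1 - w_fast) * reserve_total)
    p = (_p_from_path_rate(k_fast, rrp[0], res[0]),
         _p_from_path_rate(k_slow, rrp[1], res[1]))
    return ModelSpec(topology="parallel", n_paths=2, rrp_size_per_path=rrp,
                     reserve_size_per_path=res, p_release=p, **overrides)


def single_pool(
    k: float = K_SLOW_1HZ,
    rrp_total: float = RRP_TOTAL_DEFAULT,
    reserve_total: float = RESERVE_TOTAL_DEFAULT,
    **overrides,
) -> ModelSpec:
    """One-path model: a single, quickly mixing reserve destaining at ``k``."""
    p = _p_from_path_rate(k, rrp_total, reserve_total)
    return ModelSpec(topology="parallel", n_paths=1,
                     rrp_size_per_path=(rrp_total,),
                     reserve_size_per_path=(reserve_total,),
                     p_release=(p,), p_release_hf=(P_RELEASE_HF_DEFAULT[0],),
                     **overrides)


def default_serial(
    maturation_rate: float = 1.0 / 1800.0,
    k_fast: float = K_FAST_1HZ,
    rrp_total: float = RRP_TOTAL_DEFAULT,
    reserve_total: float = RESERVE_TOTAL_DEFAULT,
    w_fast: float = W_FAST_DEFAULT,
    **overrides,
) -> ModelSpec:
    """Serial comparator: deep reserve feeding the quickly mobilized chain.

    The quickly mobilized chain (RRP + proximal reserve) destains at
    ``k_fast``; the deep reserve backfills it and exchanges labels at
    ``maturation_rate``.  The default, 1/30 min^-1, is slow against
    ``k_fast`` (so rundown still appears at 1 Hz and the deep reserve
    retains stain over a 25-min train) yet produces measurable recovery of
    fractional destaining over minutes-long rests — the serial signature
    the rest-interval experiments probe.
    """
    res = (w_fast * reserve_total, (1 - w_fast) * reserve_total)
    p = _p_from_path_rate(k_fast, rrp_total, res[0])
    return ModelSpec(topology="serial", n_paths=2,
                     rrp_size_per_path=(rrp_total, 0.0),
                     reserve_size_per_path=res,
                     p_release=(p, 0.0),
                     p_release_hf=(P_RELEASE_HF_DEFAULT[0], 0.0),
                     maturation_rate=maturation_rate,
                     recycle_rule="return_to_source_path",
                     **overrides)


def default_lifo(
    k: float = K_FAST_1HZ,
    rrp_total: float = RRP_TOTAL_DEFAULT,
    reserve_total: float = RESERVE_TOTAL_DEFAULT,
    **overrides,
) -> ModelSpec:
    """Single reserve mobilized last-in/first-out (no intra-pool mixing)."""
    p = _p_from_path_rate(k, rrp_total, reserve_total)
    return ModelSpec(topology="lifo", n_paths=1,
                     rrp_size_per_path=(rrp_total,),
                     reserve_size_per_path=(reserve_total,),
                     p_release=(p,), p_release_hf=(P_RELEASE_HF_DEFAULT[0],),
                     recycle_rule="return_to_source_path",
                     **overrides)


@dataclass
class VesicleState:
    """Vesicle counts and per-dye labels of every pool.

    Arrays are indexed by path; ``*_labeled`` has a trailing axis of length 2
    for the two dye channels.  Unlabeled content is implicit
    (``total - labeled.sum()``).  ``cum_exo`` accumulates exocytosed vesicles
    as ``[unlabeled, dye1, dye2]``.  For the LIFO topology the reserve is an
    ordered ``stack`` of ``[amount, dye1, dye2]`` layers, newest last;
    ``reserve_total``/``reserve_labeled`` then mirror the stack sums.
    """

    rrp_total: np.ndarray
    reserve_total: np.ndarray
    rrp_labeled: np.ndarray
    reserve_labeled: np.ndarray
    cum_exo: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stack: list | None = None

    def copy(self) -> "VesicleState":
        return VesicleState(
            self.rrp_total.copy(), self.reserve_total.copy(),
            self.rrp_labeled.copy(), self.reserve_labeled.copy(),
            self.cum_exo.copy(),
            None if self.stack is None else [layer.copy() for layer in self.stack],
        )

    @property
    def total_vesicles(self) -> float:
        return float(self.rrp_total.sum() + self.reserve_total.sum())

    def fluorescence(self, channel: int = 0) -> float:
        """Summed labeled vesicle count for one dye (unit brightness)."""
        return float(self.rrp_labeled[:, channel].sum()
                     + self.reserve_labeled[:, channel].sum())

    def check(self) -> None:
        eps = -1e-9
        arrays = (self.rrp_total, self.reserve_total,
                  self.rrp_labeled, self.reserve_labeled)
        if any(np.any(a < eps) for a in arrays):
            raise ValueError("invalid state: negative pool content")
        if np.any(self.rrp_labeled.sum(axis=1) > self.rrp_total + 1e-9) or \
                np.any(self.reserve_labeled.sum(axis=1)
                       > self.reserve_total + 1e-9):
            raise ValueError("invalid state: labeled exceeds total")

    def _sync_stack_totals(self) -> None:
        arr = np.array(self.stack) if self.stack else np.zeros((0, 3))
        self.reserve_total[0] = arr[:, 0].sum()
        self.reserve_labeled[0, 0] = arr[:, 1].sum()
        self.reserve_labeled[0, 1] = arr[:, 2].sum()


def initial_state(model: ModelSpec, stained_with: int | None = None) -> VesicleState:
    """Resting state; optionally with every vesicle labeled by one dye.

    ``stained_with`` is a 0-based dye channel.  Full uniform staining is the
    idealized endpoint of the standard 60 s / 20 Hz loading protocol.
    """
    rrp = np.array(model.rrp_size_per_path, dtype=float)
    res = np.array(model.reserve_size_per_path, dtype=float)
    rrp_lab = np.zeros((model.n_paths, 2))
    res_lab = np.zeros((model.n_paths, 2))
    if stained_with is not None:
        rrp_lab[:, stained_with] = rrp
        res_lab[:, stained_with] = res
    st = VesicleState(rrp, res, rrp_lab, res_lab)
    if model.topology == "lifo":
        st.stack = [np.array([res[0], res_lab[0, 0], res_lab[0, 1]])]
    return st


# ---------------------------------------------------------------------------
# elementary updates
# ---------------------------------------------------------------------------

def _homogenize(state: VesicleState, model: ModelSpec) -> None:
    """Spread each path's labels uniformly over its RRP + reserve.

    Idealizes the fast spontaneous RRP<->reserve exchange within a path.
    Serial topology: only the proximal chain (path 0) homogenizes; LIFO: the
    stack keeps its order, only the RRP tracks the top-of-stack fraction it
    was last refilled with (no action here).
    """
    if model.topology == "lifo":
        return
    paths = range(1 if model.topology == "serial" else model.n_paths)
    for i in paths:
        n = state.rrp_total[i] + state.reserve_total[i]
        if n <= 0:
            continue
        lab = state.rrp_labeled[i] + state.reserve_labeled[i]
        f = lab / n
        state.rrp_labeled[i] = f * state.rrp_total[i]
        state.reserve_labeled[i] = f * state.reserve_total[i]


def _recycle(state: VesicleState, model: ModelSpec, amounts: np.ndarray,
             labels: np.ndarray, frequency_hz: float | None) -> None:
    """Return recycled vesicle membrane to the reserves.

    ``amounts``: vesicles recycled per source path; ``labels``: (n, 2) dye
    content they carry (bath dye or nothing).
    """
    if model.topology == "lifo":
        tot = amounts.sum()
        if tot > 0:
            layer = np.array([tot, labels[:, 0].sum(), labels[:, 1].sum()])
            top = state.stack[-1] if state.stack else None
            # merge with the top layer when the label composition matches,
            # which keeps the stack short during long uniform segments
            if top is not None and top[0] > 0 and np.allclose(
                    top[1:] / top[0], layer[1:] / layer[0], atol=1e-12):
                top += layer
            else:
                state.stack.append(layer)
            state._sync_stack_totals()
        return

    rule = model.recycle_rule
    hf = frequency_hz is not None and frequency_hz >= model.hf_threshold_hz
    if rule == "quick_first" and (hf or model.n_paths == 1):
        rule = "return_to_source_path"
    if rule == "return_to_source_path":
        state.reserve_total += amounts
        state.reserve_labeled += labels
    elif rule == "proportional_split":
        caps = np.array(model.reserve_size_per_path)
        share = caps / caps.sum()
        state.reserve_total += amounts.sum() * share
        state.reserve_labeled += labels.sum(axis=0)[None, :] * share[:, None]
    else:  # quick_first, low-frequency regime
        state.reserve_total[0] += amounts.sum()
        state.reserve_labeled[0] += labels.sum(axis=0)
        # displacement: the quickly mobilized reserve holds its resting size;
        # the inflow excess pushes quick-reserve-composition vesicles into
        # the slowly mobilized reserve (pool sizes conserved)
        cap = model.reserve_size_per_path[0]
        excess = state.reserve_total[0] - cap
        if excess > 0:
            frac = state.reserve_labeled[0] / state.reserve_total[0]
            state.reserve_total[0] -= excess
            state.reserve_labeled[0] -= excess * frac
            state.reserve_total[1] += excess
            state.reserve_labeled[1] += excess * frac


def apply_pulse(
    state: VesicleState,
    model: ModelSpec,
    dye_in_bath: int | None = None,
    frequency_hz: float | None = None,
    rng: np.random.Generator | None = None,
) -> VesicleState:
    """One action potential: exocytosis from the RRP, then recycling.

    Each readily releasable vesicle releases with the per-AP probability of
    its path (regime chosen by ``frequency_hz``).  Released stained vesicles
    destain completely; the recycled membrane re-enters a reserve pool per
    ``model.recycle_rule``, stained with ``dye_in_bath`` if a dye is present.
    Returns a new state; raises on invalid (negative) content.
    """
    state.check()
    st = state.copy()
    p = model.p_for_frequency(frequency_hz)
    if model.stochastic:
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        unlab = st.rrp_total - st.rrp_labeled.sum(axis=1)
        draws = np.stack(
            [rng.binomial(np.maximum(st.rrp_labeled[:, 0], 0).astype(int), p),
             rng.binomial(np.maximum(st.rrp_labeled[:, 1], 0).astype(int), p),
             rng.binomial(np.maximum(unlab, 0).astype(int), p)], axis=1)
        rel_lab = draws[:, :2].astype(float)
        rel_tot = draws.sum(axis=1).astype(float)
    else:
        rel_tot = p * st.rrp_total
        rel_lab = p[:, None] * st.rrp_labeled
    st.rrp_total -= rel_tot
    st.rrp_labeled -= rel_lab
    st.cum_exo[1:] += rel_lab.sum(axis=0)
    st.cum_exo[0] += rel_tot.sum() - rel_lab.sum()
    new_labels = np.zeros((model.n_paths, 2))
    if dye_in_bath is not None:
        new_labels[:, dye_in_bath] = rel_tot
    _recycle(st, model, rel_tot, new_labels, frequency_hz)
    _homogenize(st, model)
    st.check()
    return st


def _refill_rrp(state: VesicleState, model: ModelSpec, dt: float) -> None:
    """Recruit reserve vesicles into vacant RRP space.

    First-order in reserve content at ``recruit_rate`` (exact exponential
    update), stopping exactly when the RRP reaches capacity.
    """
    r = model.recruit_rate
    if r == 0.0 or dt == 0.0:
        return
    if model.topology == "lifo":
        vac = model.rrp_size_per_path[0] - state.rrp_total[0]
        avail = state.reserve_total[0] * -np.expm1(-r * dt)
        need = min(vac, avail)
        while need > 1e-15 and state.stack:
            layer = state.stack[-1]
            take = min(need, layer[0])
            frac = layer[1:] / layer[0] if layer[0] > 0 else np.zeros(2)
            layer[0] -= take
            layer[1:] -= take * frac
            if layer[0] <= 1e-12:
                state.stack.pop()
            state.rrp_total[0] += take
            state.rrp_labeled[0] += take * frac
            need -= take
        state._sync_stack_totals()
        return
    caps = np.array(model.rrp_size_per_path)
    vac = caps - state.rrp_total
    avail = state.reserve_total * -np.expm1(-r * dt)
    moved = np.minimum(np.maximum(vac, 0.0), avail)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(state.reserve_total[:, None] > 0,
                        state.reserve_labeled
                        / np.maximum(state.reserve_total, 1e-300)[:, None], 0.0)
    state.reserve_total -= moved
    state.reserve_labeled -= moved[:, None] * frac
    state.rrp_total += moved
    state.rrp_labeled += moved[:, None] * frac


def _mix_reserves(state: VesicleState, model: ModelSpec, dt: float) -> None:
    """Relax the reserves' labeled fractions toward the pooled fraction."""
    if model.topology == "lifo":
        # homogenize the stack (and RRP) toward full mixture
        a = -np.expm1(-model.mixing_rate * dt)
        arr = np.array(state.stack) if state.stack else np.zeros((0, 3))
        tot = arr[:, 0].sum() + state.rrp_total[0]
        if tot <= 0:
            return
        lab = arr[:, 1:].sum(axis=0) + state.rrp_labeled[0]
        fbar = lab / tot
        for layer in state.stack:
            layer[1:] = (1 - a) * layer[1:] + a * layer[0] * fbar
        state.rrp_labeled[0] = (1 - a) * state.rrp_labeled[0] \
            + a * state.rrp_total[0] * fbar
        state._sync_stack_totals()
        return
    if model.n_paths < 2:
        return
    _relax_labels(state, model.mixing_rate, dt)


def _relax_labels(state: VesicleState, rate: float, dt: float) -> None:
    """Exchange labels between the reserves without moving vesicles.

    Each reserve's labeled fractions relax toward the pooled fraction with
    first-order rate ``rate`` (exact exponential update); totals per pool are
    conserved, so this is pure intermixing.
    """
    decay = np.exp(-rate * dt)
    v = state.reserve_total
    if v.sum() <= 0:
        return
    fbar = state.reserve_labeled.sum(axis=0) / v.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(v[:, None] > 0,
                     state.reserve_labeled / np.maximum(v, 1e-300)[:, None], 0.0)
    f = fbar[None, :] + (f - fbar[None, :]) * decay
    state.reserve_labeled = f * v[:, None]


def _evolve(state: VesicleState, model: ModelSpec, dt: float,
            frequency_hz: float | None) -> VesicleState:
    if dt < 0:
        raise ValueError("duration must be >= 0")
    st = state.copy()
    if dt == 0.0:
        return st
    _refill_rrp(st, model, dt)
    if model.topology == "serial" and model.maturation_rate > 0:
        # deep -> proximal maturation: (a) net backfill of proximal-reserve
        # vacancy, first-order in deep content and capacity-capped, so pool
        # sizes hold their resting values; (b) label exchange at the same
        # rate (two-compartment relaxation toward the pooled fraction)
        vac = model.reserve_size_per_path[0] - st.reserve_total[0]
        avail = st.reserve_total[1] * -np.expm1(-model.maturation_rate * dt)
        moved = min(max(vac, 0.0), avail)
        if moved > 0 and st.reserve_total[1] > 0:
            frac = st.reserve_labeled[1] / st.reserve_total[1]
            st.reserve_total[1] -= moved
            st.reserve_labeled[1] -= moved * frac
            st.reserve_total[0] += moved
            st.reserve_labeled[0] += moved * frac
        _relax_labels(st, model.maturation_rate, dt)
    if model.mixing_active(frequency_hz):
        _mix_reserves(st, model, dt)
    if model.baseline_loss_rate > 0:
        decay = np.exp(-model.baseline_loss_rate * dt / 60.0)
        st.rrp_labeled *= decay
        st.reserve_labeled *= decay
        if st.stack is not None:
            for layer in st.stack:
                layer[1:] *= decay
            st._sync_stack_totals()
    _homogenize(st, model)
    st.check()
    return st


def evolve_rest(state: VesicleState, model: ModelSpec,
                duration: float) -> VesicleState:
    """Rest for ``duration`` seconds: RRP refill, maturation, mixing, drift.

    All updates are exact exponential relaxations, not Euler steps; a zero
    duration is the identity.
    """
    return _evolve(state, model, duration, frequency_hz=None)


# ---------------------------------------------------------------------------
# protocol driver
# ---------------------------------------------------------------------------

@dataclass
class SimTrace:
    """Sampled fluorescence time course of one dye channel (a.u. = vesicles)."""

    times: np.ndarray  # s, from protocol start
    F: np.ndarray
    channel: str
    sample_period: float = 4.0
    segments: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times, "channel": self.channel, "F": self.F})


@dataclass
class SimResult:
    """All channels of one simulated experiment plus segment timing."""

    times: np.ndarray
    F: dict  # channel name -> array
    segments: list  # dicts: kind, frequency_hz, t_start, t_end, dye
    final_state: VesicleState | None = None

    def trace(self, channel: int | str) -> SimTrace:
        name = _CHANNELS[channel] if isinstance(channel, int) else channel
        return SimTrace(self.times, self.F[name], name,
                        segments=self.segments)

    def to_frame(self):
        import pandas as pd

        frames = [self.trace(ch).to_frame() for ch in self.F]
        return pd.concat(frames, ignore_index=True)


def simulate(
    model: ModelSpec,
    protocol: Sequence,
    sample_period: float = 4.0,
    initial_stain: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Run a stimulation protocol and sample dye fluorescence.

    ``protocol`` is a sequence of segments with ``kind`` ("stim"/"rest"),
    ``frequency_hz``, ``duration_s`` and ``dye`` attributes (see
    :mod:`fmpools.protocols`).  Samples are taken every ``sample_period``
    seconds from protocol start; the sample at time t reflects all pulses at
    times strictly before t.  Deterministic for fixed inputs (and fixed
    ``rng`` state in stochastic mode).
    """
    segs = list(protocol)
    for s in segs:
        dye = getattr(s, "dye", None)
        if dye is not None and dye not in (0, 1):
            raise ValueError(f"invalid dye channel {dye!r}")
    state = initial_state(model, stained_with=initial_stain)
    times: list[float] = []
    F: dict[str, list[float]] = {c: [] for c in _CHANNELS}
    seg_meta = []

    t = 0.0  # global clock, s
    next_sample = 0.0

    def record():
        times.append(next_sample)
        for c_i, c in enumerate(_CHANNELS):
            F[c].append(state.fluorescence(c_i))

    for seg in segs:
        kind = getattr(seg, "kind")
        dur = float(getattr(seg, "duration_s"))
        freq = float(getattr(seg, "frequency_hz", 0.0) or 0.0)
        dye = getattr(seg, "dye", None)
        t_end = t + dur
        seg_meta.append({"kind": kind, "frequency_hz": freq,
                         "t_start": t, "t_end": t_end, "dye": dye})
        if kind == "rest" or freq == 0.0:
            while next_sample < t_end - 1e-9:
                state = _evolve(state, model, next_sample - t, None)
                t = next_sample
                record()
                next_sample += sample_period
            state = _evolve(state, model, t_end - t, None)
            t = t_end
        else:
            n_pulses = int(round(freq * dur))
            period = 1.0 / freq
            for j in range(n_pulses):
                t_pulse = t_end - dur + j * period
                while next_sample <= t_pulse + 1e-9:
                    state = _evolve(state, model, next_sample - t, freq)
                    t = next_sample
                    record()
                    next_sample += sample_period
                if t_pulse > t:
                    state = _evolve(state, model, t_pulse - t, freq)
                    t = t_pulse
                state = apply_pulse(state, model, dye_in_bath=dye,
                                    frequency_hz=freq, rng=rng)
            while next_sample < t_end - 1e-9:
                state = _evolve(state, model, next_sample - t, freq)
                t = next_sample
                record()
                next_sample += sample_period
            state = _evolve(state, model, t_end - t, freq)
            t = t_end

    return SimResult(np.asarray(times), {c: np.asarray(v) for c, v in F.items()},
                     seg_meta, final_state=state)
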