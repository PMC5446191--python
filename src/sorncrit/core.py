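"""Self-organizing recurrent network (SORN) of binary threshold units.

The network holds ``N_E`` excitatory and ``N_I = 0.2 N_E`` inhibitory
units connected by three weight matrices (E->E plastic and sparse,
I->E plastic, E->I fixed and dense).  Each discrete time step the
binary states are updated through a Heaviside threshold rule and five
plasticity mechanisms reshape the couplings:

* STDP       -- spike-timing dependent plasticity on E->E weights,
* iSTDP      -- inhibitory STDP on I->E weights,
* SN         -- synaptic normalization (incoming E and I weights of a
                unit each sum to one),
* SP         -- structural plasticity (stochastic creation of new E->E
                synapses between unconnected pairs),
* IP         -- intrinsic plasticity (homeostatic threshold adaptation
                towards a per-unit target rate).

One model time step corresponds to the STDP time scale, roughly
10-20 ms, so the default target rate of 0.1 spike/step maps to
5-10 Hz.

Conventions fixed here once and used everywhere:

* Heaviside at zero fires: ``theta(0) = 1``.
* Within-step order: state update, STDP, iSTDP, pruning of
  non-positive E->E weights, SP, IP, SN (normalization always last).
* Membrane noise drives the excitatory units; the inhibitory units are
  noise-free by default (see :class:`NoiseModel`).
* All randomness flows through named ``numpy.random.Generator``
  streams ("init", "noise", "sp", "input"); there is no global RNG
  state, which makes cloned runs bit-for-bit reproducible.

Two execution paths exist: the composable reference operations
(:func:`update_states`, :func:`stdp_update`, ... assembled by
:func:`step`) and a compiled batch kernel used by :func:`simulate` for
long runs.  The two are equivalent (the test suite checks raster
equality on shared noise streams); the kernel additionally exploits the
~10% firing sparsity and renormalizes only rows whose weights changed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol

import numpy as np
from numba import njit

__all__ = [
    "NetworkParams",
    "NoiseModel",
    "PlasticityFlags",
    "NetworkState",
    "RecordOptions",
    "SimulationRecord",
    "LetterSource",
    "make_streams",
    "init_network",
    "update_states",
    "stdp_update",
    "istdp_update",
    "prune_nonpositive",
    "synaptic_normalization",
    "structural_plasticity",
    "intrinsic_plasticity",
    "step",
    "simulate",
    "clone_state",
    "SUPRATHRESHOLD",
]

#: External drive / random-spike amplitude guaranteeing a spike.
SUPRATHRESHOLD = 1.0e7

#: Steps per noise batch in the fast loop.  Stream consumption is
#: independent of the batch boundaries (generators draw sample by
#: sample), so this is purely an implementation constant.
_BATCH = 1024

#: Rejection-sampling attempts per structural-plasticity event before
#: falling back to a deterministic scan for an unconnected pair.
_SP_TRIES = 64


# ---------------------------------------------------------------------------
# parameters, noise, flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkParams:
    """Structural and plasticity parameters of the SORN.

    Defaults are the standard operating point of the model: 200
    excitatory units, learning rates (eta_stdp, eta_inh, eta_ip) =
    (0.004, 0.001, 0.01), target rate mu_ip = 0.1 spike/step.
    """

    n_e: int = 200
    eta_stdp: float = 0.004
    eta_inh: float = 0.001
    eta_ip: float = 0.01
    eta_sp: float = 0.001
    p_sp_200: float = 0.1
    mu_ip: float = 0.1
    sigma_ip_sq: float = 0.0
    t_e_max: float = 0.5
    t_i_max: float = 1.0
    p_ee_init: float = 0.1
    p_ei_init: float = 0.2
    #: True makes inhibitory units react within the time step (y(t+1)
    #: computed from x(t+1)); the default drives them from x(t), one
    #: full step behind, exactly as the update equations read
    instant_inhibition: bool = False

    def __post_init__(self) -> None:
        if self.n_e < 5:
            raise ValueError(f"n_e={self.n_e}: need at least 5 excitatory units")
        for name in ("eta_stdp", "eta_inh", "eta_ip", "eta_sp", "sigma_ip_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_sp_200", "mu_ip", "p_ee_init", "p_ei_init"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")

    @property
    def n_i(self) -> int:
        """Number of inhibitory units, fixed at 20% of the excitatory count."""
        return int(round(0.2 * self.n_e))

    @property
    def p_sp(self) -> float:
        """Per-step synapse-creation probability, scaled with network size:
        ``p_SP(N_E) = N_E (N_E - 1) / (200 * 199) * p_SP(200)``."""
        return self.n_e * (self.n_e - 1) / (200.0 * 199.0) * self.p_sp_200


@dataclass(frozen=True)
class NoiseModel:
    """Per-step membrane noise added inside the threshold rule.

    kind
        ``"gaussian"``: i.i.d. zero-mean Gaussian with variance
        ``sigma_sq``; ``"random_spike"``: a supra-threshold kick with
        probability ``p_s`` per unit per step; ``"none"``: no noise.
    on_inhibitory
        By default the membrane noise drives the excitatory population
        only; the self-organized stable state is then reproducible
        across seeds.  Setting True adds independent noise of the same
        kind to the inhibitory units as well (this destabilizes the
        excitation/inhibition balance: runs then settle into one of
        several distinct regimes).
    active_subset
        Optional array of excitatory unit indices; when given, only
        those excitatory units receive noise.  Used by the subset-noise
        control.
    """

    kind: str = "gaussian"
    sigma_sq: float = 0.05
    p_s: float = 0.1
    on_inhibitory: bool = False
    active_subset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "random_spike", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_sq < 0:
            raise ValueError("sigma_sq must be >= 0")
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        if self.active_subset is not None:
            object.__setattr__(
                self, "active_subset", np.asarray(self.active_subset, dtype=np.intp)
            )

    def draw(self, rng: np.random.Generator, n: int, steps: int = 1) -> np.ndarray:
        """Draw a ``(steps, n)`` excitatory noise block."""
        if self.kind == "none":
            return np.zeros((steps, n))
        if self.kind == "gaussian":
            return rng.normal(0.0, np.sqrt(self.sigma_sq), size=(steps, n))
        return np.where(rng.random(size=(steps, n)) < self.p_s, SUPRATHRESHOLD, 0.0)

    def draw_inhibitory(
        self, rng: np.random.Generator, n: int, steps: int = 1
    ) -> np.ndarray:
        """Noise block for the inhibitory population (zeros by default)."""
        if not self.on_inhibitory:
            return np.zeros((steps, n))
        return self.draw(rng, n, steps)

    def mask_excitatory(self, block: np.ndarray) -> np.ndarray:
        """Restrict an excitatory noise block to ``active_subset`` (in place)."""
        if self.active_subset is None:
            return block
        keep = np.zeros(block.shape[-1], dtype=bool)
        keep[self.active_subset] = True
        block[..., ~keep] = 0.0
        return block


@dataclass(frozen=True)
class PlasticityFlags:
    """Independent switches for the five plasticity rules."""

    stdp: bool = True
    istdp: bool = True
    sn: bool = True
    sp: bool = True
    ip: bool = True

    @classmethod
    def all_on(cls) -> "PlasticityFlags":
        return cls()

    @classmethod
    def all_off(cls) -> "PlasticityFlags":
        return cls(False, False, False, False, False)

    def freeze(self, names: Iterable[str]) -> "PlasticityFlags":
        """Return a copy with the named rules switched off."""
        kw = {f: getattr(self, f) for f in ("stdp", "istdp", "sn", "sp", "ip")}
        for name in names:
            if name not in kw:
                raise ValueError(f"unknown plasticity rule {name!r}")
            kw[name] = False
        return PlasticityFlags(**kw)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """All time-varying quantities of a SORN instance.

    ``w_ee`` is dense with 0 meaning "no synapse" (pruning and
    structural plasticity edit the zero pattern).  ``mask_ei`` records
    the fixed I->E structure so iSTDP can floor a weight at zero
    without deleting the connection slot.
    """

    x: np.ndarray            # (n_e,) float 0/1 excitatory states
    y: np.ndarray            # (n_i,) float 0/1 inhibitory states
    w_ee: np.ndarray         # (n_e, n_e), entry (i, j): synapse j -> i
    w_ei: np.ndarray         # (n_e, n_i)
    mask_ei: np.ndarray      # (n_e, n_i) bool, fixed structure of w_ei
    w_ie: np.ndarray         # (n_i, n_e), fixed
    t_e: np.ndarray          # (n_e,) excitatory thresholds (plastic)
    t_i: np.ndarray          # (n_i,) inhibitory thresholds (fixed)
    h_ip: np.ndarray         # (n_e,) per-unit target rates
    t: int = 0

    @property
    def n_e(self) -> int:
        return self.w_ee.shape[0]

    @property
    def n_i(self) -> int:
        return self.w_ei.shape[1]

    def connection_fraction(self) -> float:
        """Fraction of nonzero off-diagonal E->E entries."""
        n = self.n_e
        return float(np.count_nonzero(self.w_ee)) / (n * (n - 1))


def make_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independently seeded RNG streams for one run.

    Separate streams for initialization, membrane noise, structural
    plasticity and input letters let protocols share one source of
    randomness (e.g. the same membrane noise in a plastic/frozen pair)
    while the others diverge.
    """
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("init", "noise", "sp", "input")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def clone_state(state: NetworkState) -> NetworkState:
    """Deep copy, for checkpoint/branch protocols."""
    return copy.deepcopy(state)


def init_network(params: NetworkParams, rng) -> NetworkState:
    """Random initialization of weights, thresholds and target rates.

    E->E and I->E structures are Bernoulli(``p_ee_init``) and
    Bernoulli(``p_ei_init``) (no self-connections); E->I is fully
    connected.  Weights start U[0, 0.1] and each unit's incoming
    excitatory and inhibitory weights are normalized separately to unit
    sum.  Thresholds are U[0, t_e_max] and U[0, t_i_max]; target rates
    Normal(mu_ip, sigma_ip_sq) clipped to [0, 1] (degenerate at mu_ip
    for zero variance).  States start all-zero.
    """
    if isinstance(rng, (int, np.integer)):
        rng = make_streams(int(rng))["init"]
    n_e, n_i = params.n_e, params.n_i

    struct_ee = rng.random((n_e, n_e)) < params.p_ee_init
    np.fill_diagonal(struct_ee, False)
    w_ee = np.where(struct_ee, rng.uniform(0.0, 0.1, (n_e, n_e)), 0.0)

    mask_ei = rng.random((n_e, n_i)) < params.p_ei_init
    w_ei = np.where(mask_ei, rng.uniform(0.0, 0.1, (n_e, n_i)), 0.0)

    w_ie = rng.uniform(0.0, 0.1, (n_i, n_e))

    for w in (w_ee, w_ei, w_ie):
        synaptic_normalization(w)

    t_e = rng.uniform(0.0, params.t_e_max, n_e)
    t_i = rng.uniform(0.0, params.t_i_max, n_i)
    if params.sigma_ip_sq > 0:
        h_ip = np.clip(
            rng.normal(params.mu_ip, np.sqrt(params.sigma_ip_sq), n_e), 0.0, 1.0
        )
    else:
        h_ip = np.full(n_e, params.mu_ip)

    return NetworkState(
        x=np.zeros(n_e), y=np.zeros(n_i),
        w_ee=w_ee, w_ei=w_ei, mask_ei=mask_ei, w_ie=w_ie,
        t_e=t_e, t_i=t_i, h_ip=h_ip, t=0,
    )


# ---------------------------------------------------------------------------
# reference operations (one plasticity rule each)
# ---------------------------------------------------------------------------

def update_states(
    state: NetworkState,
    u_ext: Optional[np.ndarray],
    noise: NoiseModel,
    rng: np.random.Generator,
    xi: Optional[tuple[np.ndarray, np.ndarray]] = None,
    instant_inhibition: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One threshold update; pure (the state is not touched).

    x_i(t+1) = theta[sum_j W^EE_ij x_j(t) - sum_k W^EI_ik y_k(t)
                     + u^ext_i + xi^E_i - T^E_i]
    y_k(t+1) = theta[sum_j W^IE_kj x_j(t) + xi^I_k - T^I_k]

    with theta(0) = 1.  ``instant_inhibition=True`` drives the
    inhibitory units from the freshly computed x(t+1) instead of x(t),
    removing one step of delay from the E->I->E loop.  ``xi``
    optionally injects pre-drawn (excitatory, inhibitory) noise vectors
    instead of drawing from ``rng``, e.g. to replay a recorded noise
    sequence.
    """
    if xi is not None:
        xi_e, xi_i = xi
    else:
        xi_e = noise.mask_excitatory(noise.draw(rng, state.n_e))[0]
        xi_i = noise.draw_inhibitory(rng, state.n_i)[0]
    drive_e = state.w_ee @ state.x - state.w_ei @ state.y + xi_e - state.t_e
    if u_ext is not None:
        drive_e = drive_e + u_ext
    x_next = (drive_e >= 0.0).astype(float)
    x_for_inh = x_next if instant_inhibition else state.x
    drive_i = state.w_ie @ x_for_inh + xi_i - state.t_i
    return x_next, (drive_i >= 0.0).astype(float)


def stdp_update(
    w_ee: np.ndarray, x_now: np.ndarray, x_prev: np.ndarray, eta_stdp: float
) -> np.ndarray:
    """Additive STDP on existing E->E synapses (in place; returns w_ee).

    dW_ij = eta * [x_i(t) x_j(t-1) - x_j(t) x_i(t-1)]: causal pre-post
    pairs potentiate, anti-causal pairs depress.  Only existing
    (nonzero) synapses are touched; call :func:`prune_nonpositive`
    afterwards to remove entries driven to or below zero.
    """
    post = np.flatnonzero(x_now)
    pre = np.flatnonzero(x_prev)
    if post.size and pre.size:
        blk = w_ee[post[:, None], pre]
        blk[blk > 0] += eta_stdp
        w_ee[post[:, None], pre] = blk
        blk = w_ee[pre[:, None], post]
        blk[blk > 0] -= eta_stdp
        w_ee[pre[:, None], post] = blk
    return w_ee


def prune_nonpositive(w_ee: np.ndarray) -> np.ndarray:
    """Remove E->E synapses whose weight fell to or below zero."""
    w_ee[w_ee <= 0.0] = 0.0
    return w_ee


def istdp_update(
    w_ei: np.ndarray,
    mask_ei: np.ndarray,
    x_now: np.ndarray,
    y_prev: np.ndarray,
    eta_inh: float,
    mu_ip: float,
) -> np.ndarray:
    """Inhibitory STDP on existing I->E synapses (in place).

    dW_ij = -eta_inh * y_j(t-1) * [1 - x_i(t) (1 + 1/mu_ip)]: a synapse
    whose presynaptic inhibitory unit fired is strengthened by
    eta_inh/mu_ip when the excitatory unit fires anyway, and weakened
    by eta_inh when it stays silent.  Weights are floored at zero; the
    connection slot is kept (the rule may later raise it again).
    """
    if mu_ip == 0:
        raise ValueError("mu_ip must be nonzero for the iSTDP rule")
    cols = np.flatnonzero(y_prev)
    if cols.size:
        d = eta_inh * (x_now * (1.0 + 1.0 / mu_ip) - 1.0)
        blk = w_ei[:, cols] + d[:, None] * mask_ei[:, cols]
        np.maximum(blk, 0.0, out=blk)
        w_ei[:, cols] = blk
    return w_ei


def synaptic_normalization(w: np.ndarray) -> np.ndarray:
    """Rescale every row with positive sum to unit sum (in place).

    Rows without any synapse are left untouched.
    """
    s = w.sum(axis=1)
    nz = s > 0
    w[nz] /= s[nz, None]
    return w


def structural_plasticity(
    w_ee: np.ndarray, params: NetworkParams, rng: np.random.Generator
) -> np.ndarray:
    """One Bernoulli(p_sp) trial; on success create one new synapse.

    The new synapse connects a uniformly chosen unconnected ordered
    off-diagonal pair and starts at the small weight ``eta_sp``.  If no
    unconnected pair exists the step is a no-op.
    """
    if rng.random() >= params.p_sp:
        return w_ee
    n = w_ee.shape[0]
    # rejection sampling is exact-uniform over unconnected pairs and cheap
    # at realistic connection fractions; enumerate only if the graph is dense
    for _ in range(_SP_TRIES):
        i, j = rng.integers(0, n, size=2)
        if i != j and w_ee[i, j] == 0.0:
            w_ee[i, j] = params.eta_sp
            return w_ee
    free = np.argwhere((w_ee == 0.0) & ~np.eye(n, dtype=bool))
    if free.size:
        i, j = free[rng.integers(0, len(free))]
        w_ee[i, j] = params.eta_sp
    return w_ee


def intrinsic_plasticity(
    t_e: np.ndarray, x_now: np.ndarray, h_ip: np.ndarray, eta_ip: float
) -> np.ndarray:
    """Homeostatic threshold drift dT_i = eta_ip (x_i - H_i) (in place).

    Thresholds are not clipped: the rule is self-limiting (a unit
    firing above target raises its own threshold and vice versa).
    """
    t_e += eta_ip * (x_now - h_ip)
    return t_e


def step(
    state: NetworkState,
    u_ext: Optional[np.ndarray],
    noise: NoiseModel,
    flags: PlasticityFlags,
    streams: dict[str, np.random.Generator],
    params: Optional[NetworkParams] = None,
    xi: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> NetworkState:
    """Advance the network one time step in place (reference path).

    Order: state update -> STDP -> iSTDP -> prune -> SP -> IP -> SN.
    """
    params = params or NetworkParams(n_e=state.n_e)
    x_prev, y_prev = state.x, state.y
    x_now, y_now = update_states(
        state, u_ext, noise, streams["noise"], xi=xi,
        instant_inhibition=params.instant_inhibition,
    )
    if flags.stdp:
        stdp_update(state.w_ee, x_now, x_prev, params.eta_stdp)
    if flags.istdp:
        istdp_update(
            state.w_ei, state.mask_ei, x_now, y_prev, params.eta_inh, params.mu_ip
        )
    prune_nonpositive(state.w_ee)
    if flags.sp:
        structural_plasticity(state.w_ee, params, streams["sp"])
    if flags.ip:
        intrinsic_plasticity(state.t_e, x_now, state.h_ip, params.eta_ip)
    if flags.sn:
        synaptic_normalization(state.w_ee)
        synaptic_normalization(state.w_ei)
    state.x, state.y = x_now, y_now
    state.t += 1
    return state


# ---------------------------------------------------------------------------
# compiled batch kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sorn_batch(  # noqa: C901 -- one flat kernel keeps the hot loop fast
    w_ee, w_ei, mask_ei, w_ie, t_e, t_i, h_ip, x, y,
    xi_e, xi_i,
    letters, subsets, amp,
    sp_occur, sp_cands,
    do_stdp, do_istdp, do_sn, do_sp, do_ip, instant_y,
    eta_stdp, eta_inh, eta_ip, eta_sp, mu_ip,
    x_out, act_out, nnz_out, xp_out, record_xp, nnz0,
):
    n_b = xi_e.shape[0]
    n_e = w_ee.shape[0]
    n_i = w_ei.shape[1]
    drive = np.empty(n_e)
    drive_i = np.empty(n_i)
    d_inh = np.empty(n_e)
    changed = np.zeros(n_e, dtype=np.uint8)
    fired_prev = np.empty(n_e, dtype=np.int64)
    fired_new = np.empty(n_e, dtype=np.int64)
    fired_i = np.empty(n_i, dtype=np.int64)
    n_prev = 0
    for i in range(n_e):
        if x[i] > 0.0:
            fired_prev[n_prev] = i
            n_prev += 1
    ni_prev = 0
    for k in range(n_i):
        if y[k] > 0.0:
            fired_i[ni_prev] = k
            ni_prev += 1
    nnz = nnz0
    sp_idx = 0
    # iSTDP potentiation eta_inh * ((1 + 1/mu) - 1); mu_ip = 0 is rejected
    # upstream when iSTDP is enabled
    pot = eta_inh / mu_ip if mu_ip > 0.0 else 0.0

    for b in range(n_b):
        # --- threshold update -------------------------------------------
        for i in range(n_e):
            drive[i] = xi_e[b, i] - t_e[i]
        for k in range(n_i):
            drive_i[k] = xi_i[b, k] - t_i[k]
        for jj in range(n_prev):
            j = fired_prev[jj]
            for i in range(n_e):
                drive[i] += w_ee[i, j]
            if not instant_y:
                for k in range(n_i):
                    drive_i[k] += w_ie[k, j]
        for kk in range(ni_prev):
            k = fired_i[kk]
            for i in range(n_e):
                drive[i] -= w_ei[i, k]
        if record_xp:
            # internal state: same drive without the external-input term
            for i in range(n_e):
                xp_out[b, i] = 1 if drive[i] >= 0.0 else 0
        lb = letters[b]
        if lb >= 0:
            for c in range(subsets.shape[1]):
                drive[subsets[lb, c]] += amp
        n_new = 0
        for i in range(n_e):
            if drive[i] >= 0.0:
                fired_new[n_new] = i
                n_new += 1
                x_out[b, i] = 1
            else:
                x_out[b, i] = 0
        if instant_y:
            for a in range(n_new):
                j = fired_new[a]
                for k in range(n_i):
                    drive_i[k] += w_ie[k, j]

        # --- STDP + pruning ---------------------------------------------
        if do_stdp and n_new > 0 and n_prev > 0:
            for a in range(n_new):
                i = fired_new[a]
                changed[i] = 1
                for c in range(n_prev):
                    j = fired_prev[c]
                    if w_ee[i, j] > 0.0:
                        w_ee[i, j] += eta_stdp
            for a in range(n_prev):
                i = fired_prev[a]
                changed[i] = 1
                for c in range(n_new):
                    j = fired_new[c]
                    if w_ee[i, j] > 0.0:
                        w_ee[i, j] -= eta_stdp
                        if w_ee[i, j] <= 0.0:
                            w_ee[i, j] = 0.0
                            nnz -= 1

        # --- iSTDP ---------------------------------------------------------
        ei_changed = False
        if do_istdp and ni_prev > 0:
            for i in range(n_e):
                d_inh[i] = -eta_inh
            for a in range(n_new):
                d_inh[fired_new[a]] = pot
            for kk in range(ni_prev):
                k = fired_i[kk]
                for i in range(n_e):
                    if mask_ei[i, k]:
                        w = w_ei[i, k] + d_inh[i]
                        w_ei[i, k] = w if w > 0.0 else 0.0
            ei_changed = True

        # --- structural plasticity ----------------------------------------
        if do_sp and sp_occur[b]:
            placed = False
            for c in range(sp_cands.shape[1]):
                i = sp_cands[sp_idx, c, 0]
                j = sp_cands[sp_idx, c, 1]
                if i != j and w_ee[i, j] == 0.0:
                    w_ee[i, j] = eta_sp
                    nnz += 1
                    changed[i] = 1
                    placed = True
                    break
            if not placed:
                # graph nearly complete: deterministic wrap-around scan
                start = sp_cands[sp_idx, 0, 0] * n_e + sp_cands[sp_idx, 0, 1]
                for off in range(n_e * n_e):
                    idx = (start + off) % (n_e * n_e)
                    i = idx // n_e
                    j = idx % n_e
                    if i != j and w_ee[i, j] == 0.0:
                        w_ee[i, j] = eta_sp
                        nnz += 1
                        changed[i] = 1
                        break
            sp_idx += 1

        # --- intrinsic plasticity -----------------------------------------
        if do_ip:
            for i in range(n_e):
                t_e[i] += eta_ip * (x_out[b, i] - h_ip[i])

        # --- synaptic normalization ---------------------------------------
        if do_sn:
            # only rows whose weights changed this step need rescaling
            for i in range(n_e):
                if changed[i]:
                    changed[i] = 0
                    s = 0.0
                    for j in range(n_e):
                        s += w_ee[i, j]
                    if s > 0.0:
                        inv = 1.0 / s
                        for j in range(n_e):
                            w_ee[i, j] *= inv
            if ei_changed:
                for i in range(n_e):
                    s = 0.0
                    for k in range(n_i):
                        s += w_ei[i, k]
                    if s > 0.0:
                        inv = 1.0 / s
                        for k in range(n_i):
                            w_ei[i, k] *= inv
        else:
            for i in range(n_e):
                changed[i] = 0

        # --- bookkeeping ---------------------------------------------------
        n_prev = n_new
        for a in range(n_new):
            fired_prev[a] = fired_new[a]
        ni_prev = 0
        for k in range(n_i):
            if drive_i[k] >= 0.0:
                fired_i[ni_prev] = k
                ni_prev += 1
                y[k] = 1.0
            else:
                y[k] = 0.0
        for i in range(n_e):
            x[i] = x_out[b, i]
        act_out[b] = n_new
        nnz_out[b] = nnz

    return nnz


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

class LetterSource(Protocol):
    """Per-step symbolic input: letter ids mapped to unit subsets.

    ``subsets[letter]`` lists the excitatory units driven while that
    letter is shown; ``amplitude`` is the external drive they receive.
    ``next_ids`` yields the next ``n`` letter ids (or -1 for silent
    steps), drawing any randomness from ``rng``.
    """

    subsets: np.ndarray          # (n_letters, subset_size) int
    amplitude: float

    def next_ids(self, n: int, rng: np.random.Generator) -> np.ndarray: ...


@dataclass(frozen=True)
class RecordOptions:
    """What :func:`simulate` keeps besides the activity trace.

    ``raster`` stores per-step firing-index arrays (memory heavy, for
    short runs); ``conn_every`` is the stride of the connection-fraction
    trace (0 disables); ``unit_counts`` accumulates per-unit spike
    totals; ``internal`` records the no-input internal state x'(t) used
    as the readout feature in the learning tasks.
    """

    raster: bool = False
    conn_every: int = 0
    unit_counts: bool = False
    internal: bool = False


@dataclass
class SimulationRecord:
    """Traces recorded by one :func:`simulate` call."""

    activity: np.ndarray                       # (n_steps,) int32, a(t)
    conn_steps: np.ndarray                     # steps where conn_fraction sampled
    conn_fraction: np.ndarray
    raster: Optional[list[np.ndarray]] = None  # firing indices per step
    unit_counts: Optional[np.ndarray] = None   # per-unit spike totals
    internal: Optional[np.ndarray] = None      # (n_steps, n_e) uint8 x'(t)
    letters: Optional[np.ndarray] = None       # (n_steps,) letter ids shown
    n_steps: int = 0
    n_e: int = 0
    n_i: int = 0
    seeds: dict = field(default_factory=dict)

    @property
    def mean_activity(self) -> float:
        return float(self.activity.mean())

    @property
    def mean_rate(self) -> float:
        return self.mean_activity / self.n_e if self.n_e else float("nan")


_NO_LETTERS = np.full(_BATCH, -1, dtype=np.int64)
_NO_SUBSETS = np.zeros((1, 0), dtype=np.int64)


def simulate(
    state: NetworkState,
    n_steps: int,
    params: NetworkParams,
    noise: NoiseModel,
    flags: PlasticityFlags,
    streams: dict[str, np.random.Generator],
    input_source: Optional[LetterSource] = None,
    record: RecordOptions = RecordOptions(),
    seeds: Optional[dict] = None,
) -> SimulationRecord:
    """Run the network ``n_steps`` steps in place (compiled fast path).

    ``input_source``, when given, supplies one letter id per step
    (drawing from the "input" stream); each letter drives its fixed
    unit subset with the source's amplitude.  The state is advanced in
    place; pass :func:`clone_state` output to keep the original.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if flags.istdp and params.mu_ip == 0:
        raise ValueError("mu_ip must be nonzero for the iSTDP rule")
    n_e, n_i = state.n_e, state.n_i
    if flags.sn:
        # idempotent entry normalization; afterwards the kernel only
        # renormalizes rows whose weights change
        synaptic_normalization(state.w_ee)
        synaptic_normalization(state.w_ei)

    activity = np.empty(n_steps, dtype=np.int32)
    nnz_trace = np.empty(n_steps, dtype=np.int64) if record.conn_every else None
    raster: Optional[list[np.ndarray]] = [] if record.raster else None
    unit_counts = np.zeros(n_e, dtype=np.int64) if record.unit_counts else None
    internal = np.empty((n_steps, n_e), dtype=np.uint8) if record.internal else None
    letters_rec = np.empty(n_steps, dtype=np.int64) if input_source else None

    mask_ei_u8 = state.mask_ei.astype(np.uint8)
    x_out = np.empty((_BATCH, n_e), dtype=np.uint8)
    xp_dummy = np.empty((1, n_e), dtype=np.uint8)
    nnz = int(np.count_nonzero(state.w_ee))
    rng_noise, rng_sp = streams["noise"], streams["sp"]
    rng_input = streams.get("input")

    done = 0
    while done < n_steps:
        batch = min(_BATCH, n_steps - done)
        xi_e = noise.mask_excitatory(noise.draw(rng_noise, n_e, batch))
        xi_i = noise.draw_inhibitory(rng_noise, n_i, batch)
        if input_source is not None:
            letters = np.asarray(
                input_source.next_ids(batch, rng_input), dtype=np.int64
            )
            subsets = np.ascontiguousarray(input_source.subsets, dtype=np.int64)
            amp = float(input_source.amplitude)
            letters_rec[done:done + batch] = letters
        else:
            letters = _NO_LETTERS[:batch]
            subsets, amp = _NO_SUBSETS, 0.0
        if flags.sp:
            sp_occur = rng_sp.random(batch) < params.p_sp
            n_succ = int(sp_occur.sum())
            sp_cands = rng_sp.integers(0, n_e, size=(n_succ, _SP_TRIES, 2))
        else:
            sp_occur = np.zeros(batch, dtype=bool)
            sp_cands = np.zeros((0, _SP_TRIES, 2), dtype=np.int64)

        xp_out = internal[done:done + batch] if record.internal else xp_dummy
        act_out = activity[done:done + batch]
        nnz_out = np.empty(batch, dtype=np.int64)
        nnz = _sorn_batch(
            state.w_ee, state.w_ei, mask_ei_u8, state.w_ie,
            state.t_e, state.t_i, state.h_ip, state.x, state.y,
            xi_e, xi_i,
            letters, subsets, amp,
            sp_occur, sp_cands,
            flags.stdp, flags.istdp, flags.sn, flags.sp, flags.ip,
            params.instant_inhibition,
            params.eta_stdp, params.eta_inh, params.eta_ip, params.eta_sp,
            params.mu_ip,
            x_out, act_out, nnz_out, xp_out, record.internal, nnz,
        )
        if nnz_trace is not None:
            nnz_trace[done:done + batch] = nnz_out
        if raster is not None:
            for b in range(batch):
                raster.append(np.flatnonzero(x_out[b]))
        if unit_counts is not None:
            unit_counts += x_out[:batch].sum(axis=0, dtype=np.int64)
        done += batch

    state.t += n_steps
    if record.conn_every:
        stride = record.conn_every
        idx = np.arange(0, n_steps, stride)
        conn_steps = idx + (state.t - n_steps)
        conn_fraction = nnz_trace[idx] / (n_e * (n_e - 1))
    else:
        conn_steps = np.empty(0, dtype=np.int64)
        conn_fraction = np.empty(0)
    return SimulationRecord(
        activity=activity,
        conn_steps=conn_steps,
        conn_fraction=conn_fraction,
        raster=raster,
        unit_counts=unit_counts,
        internal=internal,
        letters=letters_rec,
        n_steps=n_steps,
        n_e=n_e,
        n_i=n_i,
        seeds=dict(seeds or {}),
    )
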