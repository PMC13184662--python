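"""Discrete replicator dynamics with mutation over the full strategy simplex.

The population is represented, per preference type, as a dense mass vector over
the complete enumeration of strategy profiles.  Each time step applies, in
order: mutation (expected-mass flow through the per-element resampling kernel,
or an exact agent-resampling draw), utility evaluation against the pooled
population, and the discrete replicator reweighting followed by per-type
renormalization, so type totals are conserved exactly.

Utilities are population-weighted mean dyadic payoffs (including own-type
partners).  Because a strategy's resolved action depends only on its own
signal/attention and the partner's signal and contingent response, utilities
for all S strategies are computed in O(V * S) per step, where V is the number
of signal vectors, rather than O(S^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .model import (
    ConfigurationError,
    PreferenceType,
    ScenarioConfig,
    SignalSpace,
    StrategyProfile,
    interaction_payoff,
)

__all__ = [
    "StrategyTable",
    "PopulationState",
    "RunResult",
    "utility",
    "replicator_step",
    "mutate",
    "run",
    "analytic_two_type",
    "NumericGuardError",
]

#: minimum utility after the positivity shift (see replicator_step)
UTILITY_EPS = 1e-9


class NumericGuardError(ArithmeticError):
    """Replicator update hit a non-finite or non-positive average utility."""


@lru_cache(maxsize=32)
def _table_cached(alphabet_sizes: tuple[int, ...], n_actions: int) -> "StrategyTable":
    return StrategyTable(SignalSpace(alphabet_sizes), n_actions)


class StrategyTable:
    """Dense enumeration of every strategy profile for a space/action count.

    Strategy index = sig_index * A**C + mixed-radix(action string), with the
    first combination most significant; blocks of equal signal are contiguous.
    """

    def __init__(self, space: SignalSpace, n_actions: int):
        self.space = space
        self.n_actions = int(n_actions)
        self.n_combos = space.n_vectors
        self.n_sig = space.n_vectors
        self.n_action_maps = self.n_actions**self.n_combos
        self.size = self.n_sig * self.n_action_maps
        # all action maps, shape (A**C, C); first combo most significant
        if self.n_combos:
            grids = np.meshgrid(
                *[np.arange(self.n_actions)] * self.n_combos, indexing="ij"
            )
            self.action_maps = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
        else:  # degenerate: no combinations (cannot happen: all-null always exists)
            self.action_maps = np.zeros((1, 0), dtype=np.int64)
        self.sig_of = np.repeat(np.arange(self.n_sig), self.n_action_maps)
        self.attended = (space.vectors != 0).sum(axis=1).astype(np.int64)
        # one-hot (A**C, A) per combination, for fast action marginals
        self.action_onehot = [
            np.eye(self.n_actions)[self.action_maps[:, c]] for c in range(self.n_combos)
        ]
        # mixed-radix digits of every strategy index and the matching weights,
        # for vectorized element-wise mutation
        shape = self.mutation_axes_shape()
        self.digits = np.stack(
            np.unravel_index(np.arange(self.size), shape), axis=1
        ).astype(np.int64)
        w = np.ones(len(shape), dtype=np.int64)
        for i in range(len(shape) - 2, -1, -1):
            w[i] = w[i + 1] * shape[i + 1]
        self.digit_weights = w
        self.digit_radices = np.array(shape, dtype=np.int64)
        # perceived[obs_sig, partner_sig] -> combo index seen by the observer
        vecs = space.vectors
        masked = np.where((vecs[:, None, :] != 0), vecs[None, :, :], 0)
        radices = np.array(space.radices, dtype=np.int64)
        if space.dims:
            weights = np.cumprod(radices[::-1])[::-1]
            weights = np.concatenate([weights[1:], [1]])
            self.perceived = (masked * weights).sum(axis=2)
        else:
            self.perceived = np.zeros((1, 1), dtype=np.int64)

    @classmethod
    def for_config(cls, cfg: ScenarioConfig) -> "StrategyTable":
        return _table_cached(cfg.space.alphabet_sizes, cfg.n_actions)

    def profile(self, idx: int) -> StrategyProfile:
        sig = tuple(int(v) for v in self.space.vectors[idx // self.n_action_maps])
        acts = tuple(int(a) for a in self.action_maps[idx % self.n_action_maps])
        return StrategyProfile(self.space, sig, acts)

    def index(self, profile: StrategyProfile) -> int:
        sig_idx = self.space.vector_index(profile.signal)
        act_idx = 0
        for a in profile.actions:
            if not 0 <= a < self.n_actions:
                raise ConfigurationError(f"action {a} outside range({self.n_actions})")
            act_idx = act_idx * self.n_actions + a
        return sig_idx * self.n_action_maps + act_idx

    def mutation_axes_shape(self) -> tuple[int, ...]:
        return tuple(self.space.radices) + (self.n_actions,) * self.n_combos


@dataclass
class PopulationState:
    """Per-type mass vectors over the full strategy enumeration.

    Masses are continuous (replicator on proportions scaled by N); per-type
    totals are invariant across steps.
    """

    table: StrategyTable
    masses: np.ndarray  # shape (n_types, S)

    @property
    def type_totals(self) -> np.ndarray:
        return self.masses.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.table, self.masses.copy())

    def mass(self, type_id: int, profile: StrategyProfile) -> float:
        return float(self.masses[type_id, self.table.index(profile)])

    def counts(self, type_id: int) -> dict[str, float]:
        """Non-zero masses keyed by serialized profile (log/fixture format)."""
        row = self.masses[type_id]
        idx = np.nonzero(row)[0]
        return {self.table.profile(int(i)).to_string(): float(row[i]) for i in idx}

    @classmethod
    def from_profiles(
        cls,
        cfg: ScenarioConfig,
        assignment: dict[int, dict[StrategyProfile, float]],
    ) -> "PopulationState":
        table = StrategyTable.for_config(cfg)
        masses = np.zeros((len(cfg.types), table.size))
        for tid, profs in assignment.items():
            for prof, m in profs.items():
                masses[tid, table.index(prof)] += m
        return cls(table, masses)


@dataclass
class RunResult:
    final_state: PopulationState
    trajectory_summary: np.ndarray  # (steps_used, n_types) modal-profile share per type
    converged: bool
    steps_used: int
    seed: int
    config: ScenarioConfig = field(repr=False, default=None)

    def to_record(self) -> dict:
        """One JSON-serializable document per run."""
        cfg = self.config
        return {
            "seed": int(self.seed),
            "converged": bool(self.converged),
            "steps_used": int(self.steps_used),
            "config": None
            if cfg is None
            else {
                "name": cfg.name,
                "family": cfg.family,
                "N": cfg.N,
                "mu1": cfg.mu1,
                "mu2": cfg.mu2,
                "signal_cost": cfg.signal_cost,
                "alphabet_sizes": list(cfg.space.alphabet_sizes),
                "actions": list(cfg.action_labels),
                "types": [
                    {"label": t.label, "proportion": t.proportion, "payoffs": list(t.payoffs)}
                    for t in cfg.types
                ],
                "params": dict(cfg.params),
            },
            "final": {
                str(tid): self.final_state.counts(tid)
                for tid in range(self.final_state.masses.shape[0])
            },
        }


# ---------------------------------------------------------------------------
# utilities


def _pooled_response_table(table: StrategyTable, w_all: np.ndarray) -> np.ndarray:
    """W[sigma, c, a]: total partner weight that an ego broadcasting signal
    ``sigma`` perceives as combination ``c`` while the partner responds with
    action ``a``."""
    S = table.size
    A = table.n_actions
    C = table.n_combos
    sig = table.sig_of
    act_rows = np.arange(S) % table.n_action_maps
    W = np.empty((table.n_sig, C, A))
    for sigma in range(table.n_sig):
        cp = table.perceived[sig, sigma]  # combo each partner perceives of ego
        a_partner = table.action_maps[act_rows, cp]
        ce = table.perceived[sigma, sig]  # combo ego perceives of each partner
        W[sigma] = np.bincount(ce * A + a_partner, weights=w_all, minlength=C * A).reshape(C, A)
    return W


def _utilities(
    cfg: ScenarioConfig, table: StrategyTable, pop: PopulationState
) -> np.ndarray:
    """Expected per-interaction payoff of every strategy for every type, (n_types, S)."""
    total = pop.total
    if total <= 0:
        raise NumericGuardError("empty population")
    w_all = pop.masses.sum(axis=0) / total
    W = _pooled_response_table(table, w_all)
    C = table.n_combos
    n_types = len(cfg.types)
    util = np.empty((n_types, table.size))
    amaps = table.action_maps  # (A**C, C)
    pay = np.array([t.payoffs for t in cfg.types])  # (n_types, A)
    for sigma in range(table.n_sig):
        B = W[sigma][None, :, :] * pay[:, None, :]  # (n_types, C, A)
        block = np.zeros((n_types, table.n_action_maps))
        for c in range(C):
            block += B[:, c, :][:, amaps[:, c]]
        sl = slice(sigma * table.n_action_maps, (sigma + 1) * table.n_action_maps)
        util[:, sl] = block - cfg.signal_cost * table.attended[sigma]
    return util


def utility(
    profile: StrategyProfile,
    ptype: PreferenceType,
    pop: PopulationState,
    cfg: ScenarioConfig,
) -> float:
    """Population-weighted mean dyadic payoff of ``profile`` for ``ptype``.

    Reference implementation by direct enumeration of present partner
    profiles; the vectorized engine used inside :func:`run` is tested against
    this function.
    """
    total = pop.total
    if total <= 0:
        raise NumericGuardError("empty population")
    w_all = pop.masses.sum(axis=0)
    out = 0.0
    for i in np.nonzero(w_all)[0]:
        partner = pop.table.profile(int(i))
        out += w_all[i] * interaction_payoff(ptype, profile, partner, cfg.signal_cost)
    return out / total


def replicator_step(
    pop: PopulationState, cfg: ScenarioConfig, util: np.ndarray | None = None
) -> PopulationState:
    """One discrete replicator update, independently within each type.

    n_s <- n_s * U_s / Ubar, then rescaled so each type total is conserved.
    When a type's minimum present utility is non-positive, all of that type's
    utilities are shifted by a common constant so the minimum is UTILITY_EPS
    (rankings are preserved; documented in the methods note).
    """
    table = pop.table
    if util is None:
        util = _utilities(cfg, table, pop)
    if not np.all(np.isfinite(util)):
        raise NumericGuardError("non-finite utilities")
    new = np.zeros_like(pop.masses)
    for k in range(pop.masses.shape[0]):
        x = pop.masses[k]
        total = x.sum()
        if total <= 0:
            continue
        u = util[k].copy()
        present = x > 0
        umin = u[present].min()
        if umin <= 0:
            u = u + (UTILITY_EPS - umin)
        weighted = x * u
        z = weighted.sum()
        if z <= 0 or not np.isfinite(z):
            raise NumericGuardError(f"average utility not positive for type {k}")
        new[k] = weighted * (total / z)
    return PopulationState(table, new)


def _mutation_kernel_flow(
    table: StrategyTable, masses_row: np.ndarray, mu2: float
) -> np.ndarray:
    """Apply the per-element uniform-resampling kernel (probability mu2 per
    element) to one type's mass vector, as expected flow."""
    shape = table.mutation_axes_shape()
    x = masses_row.reshape(shape)
    for axis, radix in enumerate(shape):
        if radix == 1:
            continue
        mean = x.mean(axis=axis, keepdims=True)
        x = (1.0 - mu2) * x + mu2 * mean
    return x.reshape(-1)


def mutate(
    pop: PopulationState,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    mode: str = "expected",
) -> PopulationState:
    """Strategy-profile mutation.

    Each agent is selected with probability mu1; a selected agent has every
    element of its serialized profile independently resampled uniformly from
    that element's alphabet (null included for signal positions) with
    probability mu2.  ``expected`` mode moves the corresponding expected mass
    deterministically; ``sampled`` mode draws an exact agent-level realization
    (requires integer-valued masses).
    """
    if cfg.mu1 == 0.0 or cfg.mu2 == 0.0:
        return pop.copy()
    table = pop.table
    new = np.empty_like(pop.masses)
    if mode == "expected":
        for k in range(pop.masses.shape[0]):
            mutated = _mutation_kernel_flow(table, pop.masses[k], cfg.mu2)
            new[k] = (1.0 - cfg.mu1) * pop.masses[k] + cfg.mu1 * mutated
        return PopulationState(table, new)
    if mode != "sampled":
        raise ConfigurationError(f"unknown mutation mode {mode!r}")
    if rng is None:
        raise ConfigurationError("sampled mutation requires an rng")
    counts = np.rint(pop.masses)
    if np.abs(counts - pop.masses).max() > 1e-9:
        raise ConfigurationError("sampled mutation requires integer-valued masses")
    radices = table.digit_radices
    for k in range(counts.shape[0]):
        row = counts[k].astype(np.int64)
        sel = rng.binomial(row, cfg.mu1)
        out = row - sel
        agents = np.repeat(np.nonzero(sel)[0], sel[sel > 0])
        if agents.size:
            digits = table.digits[agents]
            hit = rng.random(digits.shape) < cfg.mu2
            draw = (rng.random(digits.shape) * radices).astype(np.int64)
            digits = np.where(hit, draw, digits)
            np.add.at(out, digits @ table.digit_weights, 1)
        new[k] = out
    return PopulationState(table, new.astype(float))


# ---------------------------------------------------------------------------
# full runs


def init_random_population(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> PopulationState:
    """Each agent's full profile string drawn uniformly over allowable values."""
    table = StrategyTable.for_config(cfg)
    counts = cfg.type_counts()
    masses = np.zeros((len(cfg.types), table.size))
    p = np.full(table.size, 1.0 / table.size)
    for k, n in enumerate(counts):
        masses[k] = rng.multinomial(int(n), p)
    return PopulationState(table, masses)


def _margins(table: StrategyTable, props: np.ndarray) -> np.ndarray:
    """Selection-relevant summary of per-type proportions: the signal marginal
    concatenated with every per-combination action marginal.

    The full profile distribution keeps drifting for a long time in
    selectively neutral directions (actions contingent on combinations a type
    never perceives), so convergence is monitored on these margins instead.
    """
    n_types = props.shape[0]
    blocks = props.reshape(n_types, table.n_sig, table.n_action_maps)
    sig_marg = blocks.sum(axis=2)
    flat = blocks.sum(axis=1)  # (n_types, A**C)
    out = [sig_marg]
    for c in range(table.n_combos):
        out.append(flat @ table.action_onehot[c])
    return np.concatenate(out, axis=1)


def _modal_pattern(table: StrategyTable, margins: np.ndarray) -> tuple:
    """Hashable summary: per type, the modal signal vector and the modal
    action for every combination *perceivable under that signal's attention*;
    unperceivable combinations are selectively neutral and would flicker at
    the sampling noise floor, so they are excluded."""
    n_types = margins.shape[0]
    sig = margins[:, : table.n_sig].argmax(axis=1)
    out = []
    for k in range(n_types):
        s = int(sig[k])
        acts = []
        for c in range(table.n_combos):
            if table.perceived[s, c] == c:
                ofs = table.n_sig + c * table.n_actions
                acts.append((c, int(margins[k, ofs : ofs + table.n_actions].argmax())))
        out.append((s, tuple(acts)))
    return tuple(out)


#: convergence of stochastic runs: the modal signal/action pattern must be
#: unchanged for PATTERN_WINDOW steps while the exponentially smoothed margins
#: drift less than DRIFT_TOL (L1, per type) over that window
PATTERN_WINDOW = 2000
DRIFT_TOL = 0.10
EMA_ALPHA = 0.02


def _relevant_combo_mask(
    cfg: ScenarioConfig, table: StrategyTable, pattern: tuple
) -> list[list[int]]:
    """Per type, the perceivable combinations whose action choice affects the
    type's own payoff against the modal profiles in ``pattern``.

    Payoff-neutral responses (e.g. a type indifferent among responses to
    partners who never adopt its valued actions) drift forever under
    mutation and must not block convergence.
    """
    space = table.space
    vecs = space.vectors
    n_actions = table.n_actions
    sigs = [tuple(int(v) for v in vecs[s]) for s, _ in pattern]
    acts = [dict(a) for _, a in pattern]
    out = []
    for i, t in enumerate(cfg.types):
        sig_i = sigs[i]
        keep = []
        for c in range(table.n_combos):
            if table.perceived[s_i := space.vector_index(sig_i), c] != c:
                continue
            pay = np.zeros(n_actions)
            for j, tj in enumerate(cfg.types):
                if tj.proportion <= 0:
                    continue
                seen_as = table.perceived[s_i, space.vector_index(sigs[j])]
                if seen_as != c:
                    continue
                partner_percept = table.perceived[space.vector_index(sigs[j]), s_i]
                a_partner = acts[j].get(int(partner_percept))
                if a_partner is None:
                    continue
                pay[a_partner] += tj.proportion * t.payoffs[a_partner]
            if pay.max() - pay.min() > 1e-12:
                keep.append(c)
        out.append(keep)
    return out


def run(
    cfg: ScenarioConfig,
    initial: PopulationState | None = None,
    mutation_mode: str | None = None,
) -> RunResult:
    """Iterate mutate -> utilities -> replicator until convergence or the step cap.

    Deterministic given ``cfg.seed``.  Two convergence criteria, whichever
    triggers first: (a) every type's per-step L1 change in its signal and
    contingent-action margins stays below ``convergence_tol`` for
    ``convergence_window`` consecutive steps (reachable by the deterministic
    expected-flow mode); (b) for the stochastic agent-resampling mode, whose
    margins fluctuate at the sampling noise floor, the modal pattern is
    unchanged and the smoothed margins have stopped drifting over a
    PATTERN_WINDOW-step window.
    """
    cfg.validate()
    mode = cfg.mutation_mode if mutation_mode is None else mutation_mode
    rng = np.random.default_rng(cfg.seed)
    pop = initial.copy() if initial is not None else init_random_population(cfg, rng)
    table = pop.table
    totals = pop.type_totals
    live = totals > 0
    safe_totals = np.where(live, totals, 1.0)
    traj = np.empty((cfg.steps, len(cfg.types)))
    window = 0
    steps_used = 0
    converged = False
    # stochastic runs need no per-step convergence bookkeeping: margins are
    # checked every CHECK_EVERY steps against the sampling-noise-robust
    # pattern/drift criterion, deterministic runs every step against the tol
    check_every = 5 if mode == "sampled" else 1
    props = pop.masses / safe_totals[:, None]
    prev_marg = _margins(table, props)
    ema = prev_marg.copy()
    n_checks = cfg.steps // check_every + 2
    ema_hist = np.empty((n_checks,) + ema.shape)
    ema_hist[0] = ema
    check_idx = 0
    pattern = _modal_pattern(table, prev_marg)
    relevant = _relevant_combo_mask(cfg, table, pattern)

    def _restrict(p, rel):
        return tuple(
            (s, tuple((c, a) for c, a in acts if c in rel[k]))
            for k, (s, acts) in enumerate(p)
        )

    last_pattern = _restrict(pattern, relevant)
    last_change = 0
    window_checks = max(PATTERN_WINDOW // check_every, 1)
    for step in range(cfg.steps):
        pop = mutate(pop, cfg, rng, mode=mode)
        util = _utilities(cfg, table, pop)
        try:
            pop = replicator_step(pop, cfg, util)
        except NumericGuardError as err:
            raise NumericGuardError(f"step {step}: {err}") from err
        if mode == "sampled":
            # agent-resampling mode: redraw an integer population from the
            # post-selection distribution, so masses stay whole agents
            for k in range(pop.masses.shape[0]):
                tot = pop.masses[k].sum()
                if tot > 0:
                    pop.masses[k] = rng.multinomial(
                        int(round(totals[k])), pop.masses[k] / tot
                    )
        traj[step] = pop.masses.max(axis=1) / safe_totals
        steps_used = step + 1
        if (step + 1) % check_every:
            continue
        props = pop.masses / safe_totals[:, None]
        marg = _margins(table, props)
        delta = np.abs(marg - prev_marg).sum(axis=1).max()
        prev_marg = marg
        ema = (1.0 - EMA_ALPHA * check_every) * ema + EMA_ALPHA * check_every * marg
        check_idx += 1
        ema_hist[check_idx] = ema
        pattern = _modal_pattern(table, marg)
        restricted = _restrict(pattern, relevant)
        if restricted != last_pattern:
            # the behaviourally relevant pattern moved: restart the stability
            # clock and refresh the relevance mask from the new pattern
            relevant = _relevant_combo_mask(cfg, table, pattern)
            last_pattern = _restrict(pattern, relevant)
            last_change = step + 1
        if delta < cfg.convergence_tol * check_every:
            window += 1
            if window >= cfg.convergence_window:
                converged = True
                break
        else:
            window = 0
        if step + 1 - last_change >= PATTERN_WINDOW and check_idx >= window_checks:
            # drift only over selection-relevant components: the signal
            # marginal plus actions on combos both perceivable under each
            # type's modal signal and payoff-relevant against the modal
            # profiles (anything else random-walks forever)
            diff = np.abs(ema_hist[check_idx] - ema_hist[check_idx - window_checks])
            drift = 0.0
            for k in range(len(pattern)):
                d = diff[k, : table.n_sig].sum()
                for c in relevant[k]:
                    ofs = table.n_sig + c * table.n_actions
                    d += diff[k, ofs : ofs + table.n_actions].sum()
                drift = max(drift, d)
            if drift < DRIFT_TOL:
                converged = True
                break
    return RunResult(
        final_state=pop,
        trajectory_summary=traj[:steps_used],
        converged=converged,
        steps_used=steps_used,
        seed=cfg.seed,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# analytic oracle for the two-type no-signal game


def analytic_two_type(V: float, d: float) -> dict[str, bool]:
    """Best-response certification of the three pure outcomes of the two-type,
    two-action, no-signal game (majority share d, preferred payoff V,
    non-preferred payoff 1).

    Returns which of {'both-preferred', 'all-majority', 'all-minority'} are
    Nash equilibria.  In a uniform-norm state a unilateral deviant
    miscoordinates with everyone (payoff 0), so both uniform norms are always
    equilibria (degenerately so when one type is absent).  In the
    both-preferred state a majority agent earns d*V and would earn (1-d)*1 by
    switching; symmetrically for the minority.
    """
    if not 0.0 <= d <= 1.0:
        raise ConfigurationError("d must be a proportion")
    out = {
        "all-majority": True,
        "all-minority": d < 1.0,
        "both-preferred": (d * V >= (1.0 - d) * 1.0) and ((1.0 - d) * V >= d * 1.0),
    }
    if d == 1.0:
        # single-type population: only its preferred norm is a distinct outcome
        out["both-preferred"] = False
    return out
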