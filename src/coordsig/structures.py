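"""Group-structure extraction, outcome classification, optimality and payoffs.

A *signalling system* maps each preference type to the signals its members
reliably broadcast; a *group structure* adds the signal-contingent actions, so
two populations can share a signalling system yet differ in structure.  A type
"reliably" signals or acts a certain way when at least ``threshold`` (default
0.90) of its mass agrees -- mutation keeps a minority of deviant profiles
alive, so exact unanimity never occurs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import PreferenceType, ScenarioConfig, SignalSpace, StrategyProfile
from .dynamics import PopulationState, StrategyTable

__all__ = [
    "TypeBehaviour",
    "SignallingSystem",
    "GroupStructure",
    "OutcomeLabel",
    "OptimalityCertificate",
    "extract_structure",
    "classify",
    "conjunctive_signalling_system",
    "is_optimal",
    "expected_payoffs",
    "render_structure",
]

DEFAULT_THRESHOLD = 0.90


@dataclass
class TypeBehaviour:
    """Modal signal and modal contingent actions of one preference type."""

    type_id: int
    label: str
    proportion: float
    signal: tuple[int, ...] | None  # None when no signal reaches the threshold
    signal_share: float
    signal_distribution: dict[tuple[int, ...], float]
    actions: dict[tuple[int, ...], int]  # combo -> modal action
    action_shares: dict[tuple[int, ...], float]
    mixed_actions: bool = False

    @property
    def mixed_signal(self) -> bool:
        return self.signal is None

    @property
    def attended(self) -> tuple[int, ...]:
        """Indices of dimensions the type reliably attends to (non-null signal)."""
        if self.signal is None:
            return ()
        return tuple(k for k, s in enumerate(self.signal) if s != 0)

    def broadcast_share(self, dim: int) -> float:
        """Fraction of the type's mass broadcasting a non-null signal in ``dim``."""
        return sum(w for s, w in self.signal_distribution.items() if s[dim] != 0)

    def profile(self, space: SignalSpace) -> StrategyProfile:
        """Representative (modal) strategy profile."""
        sig = self.signal if self.signal is not None else max(
            self.signal_distribution, key=lambda s: (self.signal_distribution[s], tuple(-x for x in s))
        )
        acts = tuple(self.actions[c] for c in space.combinations)
        return StrategyProfile(space, sig, acts)


@dataclass
class SignallingSystem:
    """Per type, the distribution over broadcast signal vectors and its mode."""

    space: SignalSpace
    per_type: dict[int, dict[tuple[int, ...], float]]
    modal: dict[int, tuple[int, ...] | None]
    threshold: float

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignallingSystem):
            return NotImplemented
        return self.modal == other.modal and self.space == other.space


@dataclass
class GroupStructure:
    """Signalling system plus per-type modal contingent-action behaviour."""

    space: SignalSpace
    behaviours: list[TypeBehaviour]
    threshold: float
    detail: str = ""

    @property
    def signalling_system(self) -> SignallingSystem:
        return SignallingSystem(
            space=self.space,
            per_type={b.type_id: dict(b.signal_distribution) for b in self.behaviours},
            modal={b.type_id: b.signal for b in self.behaviours},
            threshold=self.threshold,
        )

    def profiles(self) -> list[StrategyProfile]:
        return [b.profile(self.space) for b in self.behaviours]

    def resolved_actions(self) -> np.ndarray:
        """R[i, j] = action type i plays when meeting type j (modal profiles)."""
        profs = self.profiles()
        n = len(profs)
        out = np.zeros((n, n), dtype=int)
        for i, j in itertools.product(range(n), repeat=2):
            out[i, j] = profs[i].action_against(profs[j])
        return out

    def any_mixed(self) -> bool:
        return any(b.mixed_signal or b.mixed_actions for b in self.behaviours)

    def attention_cost(self, cost: float) -> float:
        """Population-weighted total attention cost per interaction."""
        return sum(b.proportion * cost * len(b.attended) for b in self.behaviours)


@dataclass
class OutcomeLabel:
    """Categorical outcome of one converged run, plus free-text detail.

    ``category`` is the taxonomy key used for outcome counting: the label
    itself for the named outcomes, refined by which action/type instantiates
    it, and a canonical structure signature for unnamed outcomes.
    """

    label: str
    detail: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if not self.category:
            self.category = self.label


@dataclass
class OptimalityCertificate:
    optimal: bool
    status: str  # "optimal" | "violates-i" | "violates-ii" | "violates-iii" | "undecided-iii" | "mixed"
    violations: list[str] = field(default_factory=list)
    structure_cost: float = 0.0
    best_cost: float | None = None

    def __bool__(self) -> bool:
        return self.optimal


# ---------------------------------------------------------------------------
# extraction


def extract_structure(
    pop: PopulationState, cfg: ScenarioConfig, threshold: float = DEFAULT_THRESHOLD
) -> GroupStructure:
    """Summarize a (converged) population into a GroupStructure.

    Ties are broken toward the lexicographically smallest serialization; types
    whose modal signal or modal contingent action falls below the threshold
    are flagged mixed.
    """
    table = pop.table
    space = table.space
    nA = table.n_actions
    behaviours = []
    for k, t in enumerate(cfg.types):
        row = pop.masses[k]
        total = row.sum()
        if total <= 0:
            behaviours.append(
                TypeBehaviour(k, t.label, t.proportion, tuple([0] * space.dims), 1.0,
                              {tuple([0] * space.dims): 1.0},
                              {c: 0 for c in space.combinations},
                              {c: 1.0 for c in space.combinations})
            )
            continue
        props = row / total
        # signal marginal over the contiguous per-signal blocks
        sig_marg = props.reshape(table.n_sig, table.n_action_maps).sum(axis=1)
        sig_dist = {
            tuple(int(v) for v in space.vectors[i]): float(sig_marg[i])
            for i in range(table.n_sig)
            if sig_marg[i] > 0
        }
        best = int(np.lexsort((np.arange(table.n_sig), -sig_marg))[0])
        modal_sig = tuple(int(v) for v in space.vectors[best])
        sig_share = float(sig_marg[best])
        signal = modal_sig if sig_share >= threshold else None
        # per-combination action marginals; combinations the type cannot
        # perceive under its modal attention are selectively neutral, so they
        # inherit the modal action of their masked image and do not count
        # toward the mixed flag
        actions: dict[tuple[int, ...], int] = {}
        shares: dict[tuple[int, ...], float] = {}
        mixed_actions = False
        amaps = table.action_maps
        act_rows = np.arange(table.size) % table.n_action_maps
        for c_idx, combo in enumerate(space.combinations):
            perceivable = all(c == 0 for s, c in zip(modal_sig, combo) if s == 0)
            if not perceivable:
                continue
            marg = np.zeros(nA)
            np.add.at(marg, amaps[act_rows, c_idx], props)
            a = int(np.lexsort((np.arange(nA), -marg))[0])
            actions[combo] = a
            shares[combo] = float(marg[a])
            if marg[a] < threshold:
                mixed_actions = True
        for combo in space.combinations:
            if combo not in actions:
                masked = tuple(c if s != 0 else 0 for s, c in zip(modal_sig, combo))
                actions[combo] = actions[masked]
                shares[combo] = shares[masked]
        behaviours.append(
            TypeBehaviour(
                type_id=k,
                label=t.label,
                proportion=t.proportion,
                signal=signal,
                signal_share=sig_share,
                signal_distribution=sig_dist,
                actions=actions,
                action_shares=shares,
                mixed_actions=mixed_actions,
            )
        )
    _clear_neutral_mixed_flags(behaviours, cfg, space, threshold)
    return GroupStructure(space=space, behaviours=behaviours, threshold=threshold)


def _clear_neutral_mixed_flags(behaviours, cfg, space, threshold) -> None:
    """Drop the mixed flag for action entries that are payoff-neutral.

    A type can be indifferent over its response to some perceived
    combination (e.g. a type that only values its own greeting responding to
    partners who will never adopt it); such entries drift under mutation and
    never reach the dominance threshold, but they carry no information about
    the type's behaviourally relevant strategy.  Neutrality is judged against
    the modal profiles of all types: the entry matters only if the acting
    type's own expected payoff varies across its action choices.
    """
    modal_sigs = []
    for b in behaviours:
        if b.signal is not None:
            modal_sigs.append(b.signal)
        else:
            modal_sigs.append(
                max(b.signal_distribution, key=lambda s: b.signal_distribution[s])
                if b.signal_distribution
                else tuple([0] * space.dims)
            )
    n_actions = len(cfg.action_labels)
    for i, b in enumerate(behaviours):
        if not b.mixed_actions:
            continue
        sig_i = modal_sigs[i]
        still_mixed = False
        for combo, share in b.action_shares.items():
            if share >= threshold:
                continue
            perceivable = all(c == 0 for s, c in zip(sig_i, combo) if s == 0)
            if not perceivable:
                continue
            payoff_by_action = np.zeros(n_actions)
            for j, bj in enumerate(behaviours):
                if cfg.types[j].proportion <= 0:
                    continue
                seen_as = tuple(c if s != 0 else 0 for s, c in zip(sig_i, modal_sigs[j]))
                if seen_as != combo:
                    continue
                partner_percept = tuple(
                    c if s != 0 else 0 for s, c in zip(modal_sigs[j], sig_i)
                )
                a_partner = bj.actions[partner_percept]
                payoff_by_action[a_partner] += (
                    cfg.types[j].proportion * cfg.types[i].payoffs[a_partner]
                )
            if payoff_by_action.max() - payoff_by_action.min() > 1e-12:
                still_mixed = True
                break
        b.mixed_actions = still_mixed


# ---------------------------------------------------------------------------
# payoffs


def expected_payoffs(structure: GroupStructure, cfg: ScenarioConfig) -> dict[str, float]:
    """Expected per-interaction payoff of a typical member of each type under
    random mixing, net of attention costs."""
    R = structure.resolved_actions()
    out = {}
    for i, bi in enumerate(structure.behaviours):
        ti = cfg.types[i]
        total = 0.0
        for j, bj in enumerate(structure.behaviours):
            if R[i, j] == R[j, i]:
                total += bj.proportion * ti.payoffs[R[i, j]]
        out[bi.label] = total - cfg.signal_cost * len(bi.attended)
    return out


# ---------------------------------------------------------------------------
# optimality


def _mutually_positive(t1: PreferenceType, t2: PreferenceType) -> list[int]:
    return [a for a in range(len(t1.payoffs)) if t1.payoffs[a] > 0 and t2.payoffs[a] > 0]


def _sum_max_actions(t1: PreferenceType, t2: PreferenceType) -> list[int]:
    cands = _mutually_positive(t1, t2)
    if not cands:
        return []
    best = max(t1.payoffs[a] + t2.payoffs[a] for a in cands)
    return [a for a in cands if t1.payoffs[a] + t2.payoffs[a] == best]


def _behavioural_check(
    R: np.ndarray, cfg: ScenarioConfig, pareto_variant: bool = False
) -> list[str]:
    """Clause (i) and (ii) violations of the resolved-action matrix."""
    violations = []
    n = len(cfg.types)
    for i in range(n):
        for j in range(i, n):
            t1, t2 = cfg.types[i], cfg.types[j]
            if t1.proportion <= 0 or t2.proportion <= 0:
                continue
            mp = _mutually_positive(t1, t2)
            coordinated = R[i, j] == R[j, i]
            if not mp:
                continue
            if not (coordinated and R[i, j] in mp):
                violations.append(
                    f"(i) {t1.label}-{t2.label}: no mutually beneficial coordination"
                )
                continue
            a = int(R[i, j])
            if pareto_variant:
                better = [
                    b for b in mp
                    if t1.payoffs[b] > t1.payoffs[a] and t2.payoffs[b] > t2.payoffs[a]
                ]
                if better:
                    violations.append(
                        f"(ii) {t1.label}-{t2.label}: action {a} strictly dominated"
                    )
            else:
                best = max(t1.payoffs[b] + t2.payoffs[b] for b in mp)
                if t1.payoffs[a] + t2.payoffs[a] < best:
                    violations.append(
                        f"(ii) {t1.label}-{t2.label}: action {a} not sum-maximal"
                    )
    return violations


def _feasible_signal_assignment(
    sig_choice: tuple[int, ...], cfg: ScenarioConfig, space: SignalSpace
) -> bool:
    """Whether some contingent-action assignment with the given per-type
    signal vectors satisfies optimality clauses (i) and (ii)."""
    types = cfg.types
    live = [k for k, t in enumerate(types) if t.proportion > 0]
    vecs = [tuple(int(v) for v in space.vectors[s]) for s in sig_choice]

    def perceived(obs: tuple[int, ...], par: tuple[int, ...]) -> tuple[int, ...]:
        return tuple(p if o != 0 else 0 for o, p in zip(obs, par))

    # per dyad, the admissible coordinated actions (sum-max mutually positive);
    # dyads with no mutually positive action are unconstrained.
    dyad_choices = {}
    for i in live:
        for j in live:
            if j < i:
                continue
            cands = _sum_max_actions(types[i], types[j])
            if cands:
                dyad_choices[(i, j)] = cands
    # try every combination of sum-max picks (usually a single one)
    keys = list(dyad_choices)
    for picks in itertools.product(*(dyad_choices[k] for k in keys)):
        required: dict[tuple[int, tuple[int, ...]], int] = {}
        ok = True
        for (i, j), a in zip(keys, picks):
            for ego, partner in ((i, j), (j, i)):
                combo = perceived(vecs[ego], vecs[partner])
                key = (ego, combo)
                if required.get(key, a) != a:
                    ok = False
                    break
                required[key] = a
            if not ok:
                break
        if ok:
            return True
    return False


def is_optimal(
    structure: GroupStructure,
    cfg: ScenarioConfig,
    pareto_variant: bool = False,
    search_limit: int = 10_000,
) -> OptimalityCertificate:
    """Three-clause optimality test with certificate.

    (i) every dyad with a mutually positive action coordinates on such an
    action; (ii) the coordinated action maximizes the sum of the two agents'
    payoffs (or, with ``pareto_variant``, is not strictly dominated for both);
    (iii) no structure satisfying (i)-(ii) has strictly lower total
    population-weighted attention cost, verified by exhaustive search over
    per-type signal assignments when the space has at most ``search_limit``
    candidates, else reported as undecided.
    """
    if structure.any_mixed():
        return OptimalityCertificate(False, "mixed", ["population not resolved"])
    R = structure.resolved_actions()
    violations = _behavioural_check(R, cfg, pareto_variant)
    if violations:
        status = "violates-i" if any(v.startswith("(i)") for v in violations) else "violates-ii"
        return OptimalityCertificate(False, status, violations)
    cost = structure.attention_cost(cfg.signal_cost)
    if cfg.signal_cost == 0 or cost == 0:
        return OptimalityCertificate(True, "optimal", [], cost, cost if cfg.signal_cost == 0 else 0.0)
    space = structure.space
    n_candidates = space.n_vectors ** len(cfg.types)
    if n_candidates > search_limit:
        return OptimalityCertificate(False, "undecided-iii", ["search-space overflow"], cost, None)
    best_cost = None
    props = [t.proportion for t in cfg.types]
    for sig_choice in itertools.product(range(space.n_vectors), repeat=len(cfg.types)):
        cand_cost = sum(
            p * cfg.signal_cost * int((space.vectors[s] != 0).sum())
            for p, s in zip(props, sig_choice)
        )
        if best_cost is not None and cand_cost >= best_cost:
            continue
        if _feasible_signal_assignment(sig_choice, cfg, space):
            best_cost = cand_cost
    if best_cost is None:
        # no structure satisfies (i)+(ii)?  cannot happen if this one does
        return OptimalityCertificate(True, "optimal", [], cost, cost)
    if best_cost < cost - 1e-12:
        return OptimalityCertificate(
            False, "violates-iii",
            [f"(iii) cheaper structure exists at cost {best_cost:.6g} < {cost:.6g}"],
            cost, best_cost,
        )
    return OptimalityCertificate(True, "optimal", [], cost, best_cost)


# ---------------------------------------------------------------------------
# classification


def _signature(structure: GroupStructure, cfg: ScenarioConfig) -> str:
    R = structure.resolved_actions()
    parts = []
    for i, b in enumerate(structure.behaviours):
        att = "".join("1" if k in b.attended else "0" for k in range(structure.space.dims))
        acts = "".join(str(int(R[i, j])) for j in range(len(structure.behaviours)))
        parts.append(f"{cfg.types[i].label[:2]}:{att}:{acts}")
    return "|".join(parts)


def conjunctive_signalling_system(
    structure: GroupStructure,
    conjunctive_type: int,
    parent_types: tuple[int, int],
    threshold: float = DEFAULT_THRESHOLD,
) -> bool:
    """Whether the signalling system matches the conjunctive pattern: the
    conjunctive type broadcasts in both dimensions while each parent type
    broadcasts in exactly one, distinct, dimension.

    Judged on per-dimension broadcast shares (a type broadcasts in dimension
    k iff at least ``threshold`` of its mass sends a non-null symbol there,
    and is silent iff at most 1 - threshold does).
    """
    if structure.space.dims != 2:
        return False

    def dims_of(i: int) -> tuple[int, ...] | None:
        out = []
        for k in range(2):
            share = structure.behaviours[i].broadcast_share(k)
            if share >= threshold:
                out.append(k)
            elif share > 1.0 - threshold:
                return None  # indeterminate
        return tuple(out)

    k_dims = dims_of(conjunctive_type)
    p1, p2 = (dims_of(i) for i in parent_types)
    return (
        k_dims == (0, 1)
        and p1 is not None
        and p2 is not None
        and len(p1) == 1
        and len(p2) == 1
        and p1 != p2
    )


def _conjunctive_pattern(structure: GroupStructure) -> tuple[int, int, int] | None:
    """Detect the conjunctive signalling pattern in a 2-dimensional space:
    one type broadcasting in both dimensions while two 'parent' types each
    broadcast in exactly one, distinct, dimension.  Returns the type indices
    (conjunctive, parent_dim1, parent_dim2) or None."""
    if structure.space.dims != 2:
        return None
    both = [i for i, b in enumerate(structure.behaviours) if b.attended == (0, 1)]
    only1 = [i for i, b in enumerate(structure.behaviours) if b.attended == (0,)]
    only2 = [i for i, b in enumerate(structure.behaviours) if b.attended == (1,)]
    if len(both) == 1 and len(only1) == 1 and len(only2) == 1:
        return both[0], only1[0], only2[0]
    return None


def classify(structure: GroupStructure, cfg: ScenarioConfig) -> OutcomeLabel:
    """Deterministic rule-based classification of a converged structure.

    Never raises: anything that matches no named category is returned as
    ``other`` with the canonical structure signature as its taxonomy key.
    """
    if structure.any_mixed():
        mixed = [b.label for b in structure.behaviours if b.mixed_signal or b.mixed_actions]
        # keyed by which types are unresolved, consistent with the other
        # categories carrying their instantiating type/action
        return OutcomeLabel(
            "other", f"mixed: {', '.join(mixed)}", "other:mixed:" + "+".join(mixed)
        )
    R = structure.resolved_actions()
    n = len(structure.behaviours)
    live = [i for i in range(n) if cfg.types[i].proportion > 0]
    sig = _signature(structure, cfg)
    labels = cfg.action_labels

    # uniform norm: every dyad coordinates on one and the same action
    acts = {int(R[i, j]) for i in live for j in live}
    if len(acts) == 1:
        a = acts.pop()
        largest = max(live, key=lambda i: cfg.types[i].proportion)
        kind = "majority" if cfg.types[largest].preferred_action == a else "minority"
        return OutcomeLabel(
            f"uniform-norm-{kind}",
            f"everyone coordinates on {labels[a]}",
            f"uniform-norm-{kind}:{labels[a]}",
        )

    # every type plays its own preferred action against everyone
    if all(
        int(R[i, j]) == cfg.types[i].preferred_action for i in live for j in live
    ):
        return OutcomeLabel(
            "both-preferred-miscoordination",
            "each type always gives its preferred greeting",
        )

    conj = _conjunctive_pattern(structure)
    if conj is not None and cfg.family in ("intersectional", "disjoint-double"):
        k, p1, p2 = conj
        inner = int(R[k, k])
        if inner not in (int(R[p1, p1]), int(R[p2, p2])):
            if inner == cfg.types[k].preferred_action and not _behavioural_check(R, cfg):
                return OutcomeLabel(
                    "intersectional",
                    f"{structure.behaviours[k].label} coordinate internally on "
                    f"their distinct greeting {labels[inner]}",
                )
        else:
            if not _behavioural_check(R, cfg):
                return OutcomeLabel(
                    "conjunctive-merger",
                    f"{structure.behaviours[k].label} coordinate internally on "
                    f"{labels[inner]}",
                    f"conjunctive-merger:{labels[inner]}",
                )

    behavioural_ok = not _behavioural_check(R, cfg)
    if behavioural_ok and cfg.family == "disjoint-double" and structure.space.dims == 2:
        shared = [b.signal[0] if b.signal else 0 for b in structure.behaviours]
        sumerians = [i for i in live if cfg.types[i].payoffs[0] > 0]
        if len({shared[i] for i in sumerians}) == 1 and shared[sumerians[0]] != 0:
            return OutcomeLabel(
                "disjoint-double-embedding",
                "two subgroups share a common first-dimension marker and "
                "differentiate in the second",
            )
    if behavioural_ok and cfg.family == "hierarchical-double" and structure.space.dims >= 3:
        atts = sorted((len(b.attended), i) for i, b in enumerate(structure.behaviours)
                      if cfg.types[i].payoffs[0] > 0)
        sets = [set(structure.behaviours[i].attended) for _, i in atts]
        if all(sets[k] <= sets[k + 1] for k in range(len(sets) - 1)) and len(
            {len(s) for s in sets}
        ) == len(sets):
            return OutcomeLabel(
                "hierarchical-double-embedding",
                "nested attention sets across the embedded subgroups",
            )

    if behavioural_ok:
        # optimal outcome: name it by the norm adopted in the first dyad whose
        # members hold different top preferences yet coordinate
        fav = None
        for i in live:
            for j in live:
                if i < j and cfg.types[i].preferred_action != cfg.types[j].preferred_action:
                    if R[i, j] == R[j, i] and int(R[i, j]) in (
                        cfg.types[i].preferred_action, cfg.types[j].preferred_action
                    ):
                        fav = int(R[i, j])
                        break
            if fav is not None:
                break
        name = labels[fav] if fav is not None else "none"
        return OutcomeLabel(
            f"optimal-favouring-{name}",
            "no coordination failures; preferred greetings within types",
        )

    # suboptimal lock-in where a type that ignores signals is party to a
    # coordination failure while others broadcast
    ignorers = [i for i in live if not structure.behaviours[i].attended]
    signallers = [i for i in live if structure.behaviours[i].attended]
    if ignorers and signallers:
        failures = _behavioural_check(R, cfg)
        fail_i = [v for v in failures if v.startswith("(i)")]
        blamed = sorted(
            {
                i
                for i in ignorers
                for v in fail_i
                if cfg.types[i].label in v
            }
        )
        if blamed:
            who = "+".join(cfg.types[i].label for i in blamed)
            return OutcomeLabel(
                "majority-ignores-signals-suboptimal",
                f"{who} ignore signals; {fail_i[0]}",
                f"majority-ignores-signals-suboptimal:{who}",
            )

    return OutcomeLabel("other", "unnamed structure", f"other:{sig}")


# ---------------------------------------------------------------------------
# rendering


def render_structure(structure: GroupStructure, cfg: ScenarioConfig) -> str:
    """Plain-text per-type signal -> action summary for visual inspection."""
    lines = []
    labels = cfg.action_labels
    for b in structure.behaviours:
        sig = "".join("_" if s == 0 else str(s) for s in (b.signal or ()))
        if b.mixed_signal:
            sig = "mixed"
        acts = ", ".join(
            f"{''.join('_' if s == 0 else str(s) for s in combo) or '.'}->{labels[a]}"
            for combo, a in b.actions.items()
        )
        lines.append(f"{b.label:<12} [{sig or '-'}]  {acts}")
    return "\n".join(lines)
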