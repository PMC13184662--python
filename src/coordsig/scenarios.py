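"""Preset scenarios, population initializers, named equilibrium structures and
parameter grids.

Presets are shipped as YAML files (one per scenario family); payoff entries
and proportions may be arithmetic expressions over the preset's declared free
parameters (e.g. ``V``, ``d``, ``r``), which :func:`preset` resolves after
applying user overrides.
"""

from __future__ import annotations

import csv
import itertools
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .model import (
    ConfigurationError,
    PreferenceType,
    ScenarioConfig,
    SignalSpace,
    StrategyProfile,
)
from .dynamics import PopulationState, StrategyTable, init_random_population
from .structures import GroupStructure, TypeBehaviour

__all__ = [
    "PRESET_NAMES",
    "preset",
    "load_config",
    "save_config",
    "init_population",
    "named_structure",
    "structure_profiles",
    "parameter_grid",
    "write_grid_manifest",
]

PRESET_NAMES = (
    "two-type-base",
    "three-type-cost",
    "single-embedding",
    "intersectional",
    "disjoint-double",
    "hierarchical-double",
)

#: overrides accepted by :func:`preset` beyond each preset's free parameters
_RUN_OVERRIDES = {
    "c",
    "mu1",
    "mu2",
    "N",
    "seed",
    "steps",
    "signal_alphabet",
    "convergence_tol",
    "convergence_window",
    "mutation_mode",
}

STRUCTURED_NOISE_EPS = 0.01


def _eval(expr, params: dict) -> float:
    if isinstance(expr, (int, float)):
        return float(expr)
    try:
        return float(eval(expr, {"__builtins__": {}}, dict(params)))  # noqa: S307
    except Exception as err:  # pragma: no cover - malformed preset
        raise ConfigurationError(f"cannot evaluate expression {expr!r}: {err}") from err


def _load_preset_doc(name: str) -> dict:
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("coordsig").joinpath(f"presets/{name}.yaml").read_text()
    return yaml.safe_load(text)


def _config_from_doc(doc: dict, overrides: dict | None = None) -> ScenarioConfig:
    overrides = dict(overrides or {})
    free = dict(doc.get("free_parameters", {}))
    allowed = set(free) | _RUN_OVERRIDES
    bad = set(overrides) - allowed
    if bad:
        raise ConfigurationError(
            f"invalid overrides {sorted(bad)}; allowed: {sorted(allowed)}"
        )
    params = {k: overrides.get(k, v) for k, v in free.items()}
    types = []
    for i, spec in enumerate(doc["types"]):
        types.append(
            PreferenceType(
                id=i,
                label=spec["label"],
                payoffs=tuple(_eval(p, params) for p in spec["payoffs"]),
                proportion=_eval(spec["proportion"], params),
            )
        )
    alphabet = overrides.get("signal_alphabet", doc.get("signal_alphabet", []))
    cfg = ScenarioConfig(
        types=types,
        action_labels=tuple(doc["actions"]),
        space=SignalSpace(tuple(alphabet)),
        signal_cost=float(overrides.get("c", doc.get("signal_cost", 0.0))),
        N=int(overrides.get("N", doc.get("N", 1000))),
        mu1=float(overrides.get("mu1", doc.get("mu1", 0.1))),
        mu2=float(overrides.get("mu2", doc.get("mu2", 0.1))),
        steps=int(overrides.get("steps", doc.get("steps", 6000))),
        convergence_tol=float(overrides.get("convergence_tol", doc.get("convergence_tol", 1e-6))),
        convergence_window=int(
            overrides.get("convergence_window", doc.get("convergence_window", 25))
        ),
        mutation_mode=str(overrides.get("mutation_mode", doc.get("mutation_mode", "sampled"))),
        seed=int(overrides.get("seed", 0)),
        family=doc.get("family", doc["name"]),
        name=doc["name"],
        params=params,
    )
    return cfg.validate()


def preset(name: str, overrides: dict | None = None) -> ScenarioConfig:
    """A fully validated configuration for one of the shipped scenarios.

    ``overrides`` may set the preset's free parameters (e.g. V, d, r, VK) and
    the run parameters c, mu1, mu2, N, seed, steps, signal_alphabet,
    convergence_tol, convergence_window.
    """
    return _config_from_doc(_load_preset_doc(name), overrides)


def load_config(path: str | Path, overrides: dict | None = None) -> ScenarioConfig:
    """Load a user scenario file written in the preset dialect."""
    doc = yaml.safe_load(Path(path).read_text())
    return _config_from_doc(doc, overrides)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    doc = {
        "name": cfg.name,
        "family": cfg.family,
        "actions": list(cfg.action_labels),
        "signal_alphabet": list(cfg.space.alphabet_sizes),
        "signal_cost": cfg.signal_cost,
        "N": cfg.N,
        "mu1": cfg.mu1,
        "mu2": cfg.mu2,
        "steps": cfg.steps,
        "free_parameters": dict(cfg.params),
        "types": [
            {"label": t.label, "proportion": t.proportion, "payoffs": list(t.payoffs)}
            for t in cfg.types
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# named structures (used for structured initial conditions and as analysis
# fixtures for the equilibria discussed alongside each scenario)


def _behaviour(
    cfg: ScenarioConfig,
    type_id: int,
    signal: tuple[int, ...],
    responses: dict[tuple[int, ...], int],
) -> TypeBehaviour:
    """Build a resolved TypeBehaviour from responses on *perceived* combos.

    ``responses`` maps each combination the type can actually perceive (given
    its own attention) to an action; unperceivable combinations inherit the
    action of their masked image, making the contingent map total.
    """
    space = cfg.space
    actions = {}
    for combo in space.combinations:
        masked = tuple(c if s != 0 else 0 for s, c in zip(signal, combo))
        actions[combo] = responses[masked]
    t = cfg.types[type_id]
    return TypeBehaviour(
        type_id=type_id,
        label=t.label,
        proportion=t.proportion,
        signal=signal,
        signal_share=1.0,
        signal_distribution={signal: 1.0},
        actions=actions,
        action_shares={c: 1.0 for c in space.combinations},
    )


def _structure(cfg: ScenarioConfig, spec: dict[int, tuple[tuple[int, ...], dict]]) -> GroupStructure:
    behaviours = [
        _behaviour(cfg, tid, sig, resp) for tid, (sig, resp) in sorted(spec.items())
    ]
    return GroupStructure(space=cfg.space, behaviours=behaviours, threshold=1.0)


def _intersectional_structures(cfg: ScenarioConfig) -> dict[str, GroupStructure]:
    # actions: 0 umma, 1 lagash, 2 kish, 3 akkad; types: 0 U, 1 L, 2 K, 3 A
    a = {"umma": 0, "lagash": 1, "kish": 2, "akkad": 3}
    base = {
        0: ((1, 0), {(0, 0): a["akkad"], (1, 0): a["umma"]}),
        1: ((0, 1), {(0, 0): a["akkad"], (0, 1): a["lagash"]}),
        3: ((0, 0), {(0, 0): a["akkad"]}),
    }
    out = {}
    for name, inner in (
        ("intersectional", a["kish"]),
        ("conjunction-umma", a["umma"]),
        ("conjunction-lagash", a["lagash"]),
    ):
        spec = dict(base)
        spec[2] = (
            (1, 1),
            {
                (0, 0): a["akkad"],
                (1, 0): a["umma"],
                (0, 1): a["lagash"],
                (1, 1): inner,
            },
        )
        out[name] = _structure(cfg, spec)
    return out


def _three_type_structures(cfg: ScenarioConfig) -> dict[str, GroupStructure]:
    # actions: 0 umma, 1 kish, 2 akkad; types: 0 U, 1 K, 2 A; signals {0,1,2}
    out = {}
    for name, cross in (("optimal-favouring-umma", 0), ("optimal-favouring-kish", 1)):
        out[name] = _structure(
            cfg,
            {
                0: ((1,), {(0,): 2, (1,): 0, (2,): cross}),
                1: ((2,), {(0,): 2, (1,): cross, (2,): 1}),
                2: ((0,), {(0,): 2}),
            },
        )
    # prominent suboptimal outcome: Ummians ignore signals and always give the
    # Umma greeting; Kishus condition on everyone; Akkadians signal but always
    # give the Akkadian greeting
    out["majority-ignores"] = _structure(
        cfg,
        {
            0: ((0,), {(0,): 0}),
            1: ((1,), {(0,): 0, (1,): 1, (2,): 2}),
            2: ((2,), {(0,): 2, (1,): 2, (2,): 2}),
        },
    )
    return out


def _single_embedding_structures(cfg: ScenarioConfig) -> dict[str, GroupStructure]:
    # actions: 0 girsu, 1 lagash, 2 akkad; types: 0 G, 1 L, 2 A
    out = {}
    if cfg.space.alphabet_sizes == (1, 1):
        out["optimal-two-dim"] = _structure(
            cfg,
            {
                0: ((1, 1), {(0, 0): 2, (1, 0): 1, (0, 1): 0, (1, 1): 0}),
                1: ((1, 0), {(0, 0): 2, (1, 0): 1}),
                2: ((0, 0), {(0, 0): 2}),
            },
        )
    elif cfg.space.alphabet_sizes == (2,):
        out["optimal-one-dim"] = _structure(
            cfg,
            {
                0: ((2,), {(0,): 2, (1,): 1, (2,): 0}),
                1: ((1,), {(0,): 2, (1,): 1, (2,): 1}),
                2: ((0,), {(0,): 2}),
            },
        )
    return out


def _disjoint_structures(cfg: ScenarioConfig) -> dict[str, GroupStructure]:
    # actions: 0 sumerian, 1 umma, 2 lagash, 3 akkad; types: 0 S, 1 U, 2 L, 3 A
    return {
        "disjoint": _structure(
            cfg,
            {
                0: ((1, 0), {(0, 0): 3, (1, 0): 0}),
                1: ((1, 1), {(0, 0): 3, (1, 0): 0, (1, 1): 1, (1, 2): 0, (0, 1): 1, (0, 2): 0}),
                2: ((1, 2), {(0, 0): 3, (1, 0): 0, (1, 1): 0, (1, 2): 2, (0, 1): 0, (0, 2): 2}),
                3: ((0, 0), {(0, 0): 3}),
            },
        )
    }


def _hierarchical_structures(cfg: ScenarioConfig) -> dict[str, GroupStructure]:
    # actions: 0 sumerian, 1 lagash, 2 girsu, 3 akkad; types: 0 S, 1 L, 2 G, 3 A
    def g_resp(c):
        if c[2] == 1:
            return 2
        if c[1] == 1:
            return 1
        if c[0] == 1:
            return 0
        return 3

    def l_resp(c):
        if c[1] == 1:
            return 1
        if c[0] == 1:
            return 0
        return 3

    combos3 = list(itertools.product((0, 1), repeat=3))
    return {
        "hierarchical": _structure(
            cfg,
            {
                0: ((1, 0, 0), {(0, 0, 0): 3, (1, 0, 0): 0}),
                1: ((1, 1, 0), {c: l_resp(c) for c in combos3 if c[2] == 0}),
                2: ((1, 1, 1), {c: g_resp(c) for c in combos3}),
                3: ((0, 0, 0), {(0, 0, 0): 3}),
            },
        )
    }


_STRUCTURE_BUILDERS = {
    "intersectional": _intersectional_structures,
    "three-type-cost": _three_type_structures,
    "single-embedding": _single_embedding_structures,
    "disjoint-double": _disjoint_structures,
    "hierarchical-double": _hierarchical_structures,
}


def named_structure(cfg: ScenarioConfig, name: str) -> GroupStructure:
    """A named reference GroupStructure for the scenario family of ``cfg``."""
    builder = _STRUCTURE_BUILDERS.get(cfg.family)
    if builder is None:
        raise ConfigurationError(f"no named structures for family {cfg.family!r}")
    table = builder(cfg)
    if name not in table:
        raise ConfigurationError(
            f"unknown structure {name!r} for {cfg.family}; choose from {sorted(table)}"
        )
    return table[name]


def structure_profiles(structure: GroupStructure) -> list[StrategyProfile]:
    return structure.profiles()


# ---------------------------------------------------------------------------
# population initialization


def init_population(
    cfg: ScenarioConfig,
    mode: str = "random",
    rng: np.random.Generator | None = None,
    structure: "GroupStructure | str | None" = None,
    eps: float = STRUCTURED_NOISE_EPS,
) -> PopulationState:
    """Initial PopulationState.

    ``random`` draws each agent's full profile string uniformly over allowable
    element values; ``structured`` places mass 1 - eps of each type on the
    profile of a seeded GroupStructure (given directly or by name) and spreads
    the remaining eps uniformly over all profiles.
    """
    if mode == "random":
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        return init_random_population(cfg, rng)
    if mode != "structured":
        raise ConfigurationError(f"unknown initialization mode {mode!r}")
    if structure is None:
        raise ConfigurationError("structured initialization needs a structure")
    if isinstance(structure, str):
        structure = named_structure(cfg, structure)
    if structure.space != cfg.space:
        raise ConfigurationError("structure signal space incompatible with scenario")
    table = StrategyTable.for_config(cfg)
    counts = cfg.type_counts()
    masses = np.zeros((len(cfg.types), table.size))
    profiles = structure.profiles()
    for k, n in enumerate(counts):
        masses[k] = n * eps / table.size
        masses[k, table.index(profiles[k])] += n * (1.0 - eps)
    return PopulationState(table, masses)


# ---------------------------------------------------------------------------
# parameter grids


def parameter_grid(
    preset_name: str,
    axes: dict[str, list] | None = None,
    base_seed: int = 0,
    overrides: dict | None = None,
) -> list[ScenarioConfig]:
    """Cartesian product of named parameter ranges, row-major, with seeds
    assigned deterministically from ``base_seed``."""
    axes = axes or {}
    names = list(axes)
    values = [list(axes[n]) for n in names]
    configs = []
    for i, combo in enumerate(itertools.product(*values)):
        ov = dict(overrides or {})
        ov.update(dict(zip(names, combo)))
        ov["seed"] = (int(base_seed) + 1000003 * i) % (2**31)
        configs.append(preset(preset_name, ov))
    return configs


def write_grid_manifest(configs: list[ScenarioConfig], path: str | Path) -> None:
    """CSV manifest: one row per config with its free parameters and seed."""
    keys = sorted({k for cfg in configs for k in cfg.params})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "name", *keys, "seed"])
        for i, cfg in enumerate(configs):
            writer.writerow([i, cfg.name, *[cfg.params.get(k, "") for k in keys], cfg.seed])
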