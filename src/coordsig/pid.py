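"""Partial information decomposition of the two signal dimensions.

Used to diagnose intersectional group structures: a structure is
intersectional to the extent that the two signalling dimensions carry
*synergistic* information -- information available only from the combination
of both signals -- about who the signaller is and how they coordinate.

Two bivariate redundancy measures are provided:

``mmi``
    minimum-mutual-information redundancy, R = min(I(S1;T), I(S2;T)), so the
    synergy is I(S1,S2;T) - max(I(S1;T), I(S2;T)).  This is the measure used
    for the headline synergy fractions.
``wb``
    the Williams-Beer I_min built from specific information, the original
    PID redundancy.

Both satisfy the lattice identities: unique_i = I(Si;T) - R and
synergy = I(S1,S2;T) - unique_1 - unique_2 - R, with all four components
non-negative and summing to the total mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ConfigurationError, DimensionalityError, ScenarioConfig
from .structures import GroupStructure

__all__ = [
    "JointDistribution",
    "PIDResult",
    "joint_from_structure",
    "pid_synergy",
    "mutual_information",
]

_ATOL = 1e-12


@dataclass
class JointDistribution:
    """Probability mass p(s1, s2, t) over the two signal symbols and a target."""

    p: np.ndarray  # shape (n_s1, n_s2, n_t)
    target_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 3:
            raise DimensionalityError("joint distribution must be 3-dimensional")
        if np.any(self.p < -_ATOL):
            raise ConfigurationError("negative probability mass")
        self.p = np.clip(self.p, 0.0, None)
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"mass sums to {self.p.sum()}, not 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n1, n2, nt = self.p.shape
        for i in range(n1):
            for j in range(n2):
                for t in range(nt):
                    if self.p[i, j, t] > 0:
                        label = self.target_labels[t] if self.target_labels else str(t)
                        rows.append({"s1": i, "s2": j, "T": label, "p": self.p[i, j, t]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "JointDistribution":
        df = pd.read_csv(path)
        labels = sorted(df["T"].astype(str).unique())
        shape = (int(df.s1.max()) + 1, int(df.s2.max()) + 1, len(labels))
        p = np.zeros(shape)
        for _, row in df.iterrows():
            p[int(row["s1"]), int(row["s2"]), labels.index(str(row["T"]))] += row["p"]
        return cls(p, tuple(labels))


@dataclass
class PIDResult:
    total: float
    redundancy: float
    unique_1: float
    unique_2: float
    synergy: float
    redundancy_measure: str = "mmi"
    degenerate: bool = False

    @property
    def synergy_fraction(self) -> float:
        return self.synergy / self.total if self.total > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "total_bits": self.total,
            "redundancy_bits": self.redundancy,
            "unique_1_bits": self.unique_1,
            "unique_2_bits": self.unique_2,
            "synergy_bits": self.synergy,
            "synergy_fraction": self.synergy_fraction,
            "redundancy_measure": self.redundancy_measure,
            "degenerate": self.degenerate,
        }


def mutual_information(pxy: np.ndarray) -> float:
    """I(X;Y) in bits from a 2-d joint table; zero cells contribute zero."""
    pxy = np.asarray(pxy, dtype=float)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return float(np.nansum(terms))


def _wb_imin(p: np.ndarray) -> float:
    """Williams-Beer I_min redundancy of sources S1, S2 about T."""
    pt = p.sum((0, 1))
    red = 0.0
    for t in range(p.shape[2]):
        if pt[t] <= 0:
            continue
        specs = []
        for axis in (1, 0):  # marginalize out the other source
            pst = p.sum(axis=axis)  # (n_s, n_t)
            ps = pst.sum(axis=1)
            spec = 0.0
            for s in range(pst.shape[0]):
                if pst[s, t] > 0:
                    spec += (pst[s, t] / pt[t]) * np.log2(pst[s, t] / (ps[s] * pt[t]))
            specs.append(spec)
        red += pt[t] * min(specs)
    return red


def pid_synergy(joint: JointDistribution | np.ndarray, redundancy: str = "mmi") -> PIDResult:
    """Partial information decomposition of two sources about the target.

    Logarithms are base 2; zero-probability cells contribute zero.  A joint
    with zero total mutual information is reported with synergy fraction 0
    and the degenerate flag set.
    """
    p = joint.p if isinstance(joint, JointDistribution) else np.asarray(joint, float)
    if p.ndim != 3:
        raise DimensionalityError("need p(s1, s2, t)")
    p = p / p.sum()
    i1 = mutual_information(p.sum(axis=1))
    i2 = mutual_information(p.sum(axis=0))
    itot = mutual_information(p.reshape(-1, p.shape[2]))
    if redundancy == "mmi":
        red = min(i1, i2)
    elif redundancy == "wb":
        red = _wb_imin(p)
    else:
        raise ConfigurationError(f"unknown redundancy measure {redundancy!r}")
    u1 = max(i1 - red, 0.0)
    u2 = max(i2 - red, 0.0)
    syn = max(itot - i1 - i2 + red, 0.0)
    degenerate = itot <= 1e-12
    return PIDResult(
        total=itot,
        redundancy=red,
        unique_1=u1,
        unique_2=u2,
        synergy=syn,
        redundancy_measure=redundancy,
        degenerate=degenerate,
    )


def joint_from_structure(
    structure: GroupStructure, cfg: ScenarioConfig, target: str = "norm"
) -> JointDistribution:
    """Joint distribution p(s1, s2, T) implied by a group structure.

    Each type contributes its population share at its modal signal vector (or
    its full signal mixture when no signal reaches the dominance threshold).
    ``target`` selects the third variable:

    ``norm``
        the in-group coordination norm -- the action a type plays upon
        perceiving its own signal combination.  Types whose members behave
        identically inside their group share a target value, so this is the
        identity an observer could attribute from behaviour.
    ``type``
        the latent preference type itself.
    """
    space = structure.space
    if space.dims < 2:
        raise DimensionalityError("need at least two signalling dimensions for PID")
    if space.dims != 2:
        raise DimensionalityError("decomposition is defined for exactly two dimensions")
    n1, n2 = space.radices
    if target == "type":
        n_t = len(structure.behaviours)
        labels = tuple(b.label for b in structure.behaviours)
    elif target == "norm":
        n_t = len(cfg.action_labels)
        labels = tuple(cfg.action_labels)
    else:
        raise ConfigurationError(f"unknown target {target!r}")
    p = np.zeros((n1, n2, n_t))
    for b in structure.behaviours:
        if b.proportion <= 0:
            continue
        sig_dist = (
            {b.signal: 1.0} if b.signal is not None else dict(b.signal_distribution)
        )
        for sig, w in sig_dist.items():
            if target == "type":
                t_val = b.type_id
            else:
                own_perceived = tuple(
                    c if s != 0 else 0 for s, c in zip(sig, sig)
                )  # own signal masked by own attention = own signal
                t_val = b.actions[own_perceived]
            p[sig[0], sig[1], t_val] += b.proportion * w
    return JointDistribution(p, labels)
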