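"""Dynamical-system simulation of alloreactive donor T cell responses.

Each donor T cell clone grows logistically toward a steady state set by
"signal 1": the product of the presenting complex's peptide-HLA affinity
B = 1/IC50, the clone's TCR affinity Z = 1/IC50, the tissue expression P of
the source protein, a scavenging attenuation c (c = 1 for class I
cytosolic loading, 0 < c < 1 for class II endocytic loading), and the
system carrying capacity K:

    N_t = K' * N_0 / ((K' - N_{t-1}) * exp(-r * t * B) + 1),
    K'  = P * c * K * B * Z.

The rate r composes the checkpoint gate CP (PD1 engaged -> 0), the
costimulation gate S2 (CD28 -> 1, CTLA4 -> 0) and the net cytokine signal
Ck: r = CP * (S2 * Ck).  When r = 0 the exponential is 1 and a clone
started at N_0 = 1 is arrested at 1 exactly; a negative Ck (suppressive
field) makes the clone decay.

Clone-antigen coupling is the alloreactivity tensor: the n x m matrix with
entries B_i * Z_j * recognition(i, j).  Iterating the logistic rule over
this tensor transforms the infused repertoire; the aggregate response is
the per-clone sum at each step.  An optional cytokine amplification
multiplies each step by Ck^(t * (1 - N_{t-1}/K')), boosting early growth
and fading to 1 as the clone approaches its steady state.

The clinical probability of an alloreactive response against a given
peptide is the product of the cleavage, presentation-competition and
clone-presence probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


def ic50_to_affinity(ic50: float) -> float:
    """Affinity in nM^-1 from an IC50 in nM (B or Z = 1/IC50)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    return 1.0 / ic50


@dataclass(frozen=True)
class AntigenParams:
    """One peptide-HLA complex: affinity B (nM^-1), tissue expression P
    (RPKM), and the class II scavenging constant c (1 for class I)."""

    antigen_id: str
    b_affinity: float
    expression: float = 1.0
    scavenging: float = 1.0

    def __post_init__(self) -> None:
        if self.b_affinity <= 0:
            raise ValueError("b_affinity must be positive")
        if not (0 < self.scavenging <= 1):
            raise ValueError("scavenging constant c must be in (0, 1]")
        if self.expression < 0:
            raise ValueError("expression must be non-negative")


@dataclass(frozen=True)
class CloneParams:
    """One donor T cell clone: TCR affinity Z (nM^-1), initial count N_0,
    carrying capacity K, and its binary checkpoint/costimulation state."""

    clone_id: str
    z_affinity: float
    carrying_capacity: float
    n0: float = 1.0
    cp: int = 1           # 0 = PD1 engaged (arrest)
    s2: int = 1           # 1 = CD28, 0 = CTLA4 (arrest)
    receptor_levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.z_affinity <= 0:
            raise ValueError("z_affinity must be positive")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.cp not in (0, 1) or self.s2 not in (0, 1):
            raise ValueError("cp and s2 must be binary")


@dataclass(frozen=True)
class CytokineField:
    """Diagonal cytokine tensor: (level, receptor level, sign) per
    cytokine-receptor pair; sign -1 marks growth-suppressive cytokines."""

    entries: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        for level, receptor, sign in self.entries:
            if level < 0 or receptor < 0:
                raise ValueError("cytokine and receptor levels must be >= 0")
            if sign not in (-1, 1):
                raise ValueError("sign must be +1 or -1")


def cytokine_net(
    fld: CytokineField,
    receptor_levels: Sequence[float] | None = None,
) -> float:
    """Net cytokine signal Ck = sum_i sign_i * cytokine_i * receptor_i.

    ``receptor_levels`` overrides the field's stored receptor levels (e.g.
    with a clone's own receptor expression); its length must match.
    """
    if receptor_levels is None:
        return float(sum(s * c * r for c, r, s in fld.entries))
    if len(receptor_levels) != len(fld.entries):
        raise ValueError(
            f"{len(receptor_levels)} receptor levels for "
            f"{len(fld.entries)} cytokine entries")
    return float(sum(s * c * r for (c, _, s), r
                     in zip(fld.entries, receptor_levels)))


def compose_r(cp: int, s2: int, ck: float) -> float:
    """Growth rate r = CP * (S2 * Ck); zero under PD1 or CTLA4 engagement."""
    return cp * s2 * ck


def k_prime(antigen: AntigenParams, clone: CloneParams) -> float:
    """Steady-state scale K' = P * c * K * B * Z."""
    return (antigen.expression * antigen.scavenging
            * clone.carrying_capacity * antigen.b_affinity
            * clone.z_affinity)


def logistic_step(
    n_prev: float,
    t: int,
    antigen: AntigenParams,
    clone: CloneParams,
    r: float,
) -> float:
    """One iteration of the logistic growth rule.

    With r * B > 0 the sequence converges to K' * N_0 (relative error is
    bounded by exp(-r * t * B)); with r = 0 and N_0 = 1 the clone is fixed
    at 1 (growth arrest).  A non-positive denominator (over-capacity start
    against a decaying exponential) is clamped to the steady state with a
    warning.
    """
    if n_prev < 0:
        raise ValueError("n_prev must be non-negative")
    kp = k_prime(antigen, clone)
    denom = (kp - n_prev) * math.exp(-r * t * antigen.b_affinity) + 1.0
    if denom <= 0:
        warnings.warn(
            "non-positive logistic denominator; clamping to steady state",
            stacklevel=2)
        return kp * clone.n0
    return kp * clone.n0 / denom


def cytokine_amplified_step(
    n_prev: float,
    t: int,
    antigen: AntigenParams,
    clone: CloneParams,
    r: float,
    ck: float,
) -> float:
    """Logistic step scaled by the cytokine amplification factor
    Ck^(t * (1 - N_{t-1}/K')).

    Early on (N far below K') abundant cytokines multiply growth; the
    exponent shrinks to 0 as the clone approaches K', so the factor fades
    to 1 and the steady state is unchanged.  Requires Ck >= 0 (suppression
    enters through r, not through the amplification)."""
    if ck < 0:
        raise ValueError("cytokine amplification requires Ck >= 0")
    base = logistic_step(n_prev, t, antigen, clone, r)
    kp = k_prime(antigen, clone)
    factor = ck ** (t * (1.0 - n_prev / kp))
    return factor * base


@dataclass(frozen=True)
class AlloTensor:
    """Alloreactivity tensor: entries[i, j] = B_i * Z_j * recognition(i, j)."""

    entries: np.ndarray                # n antigens x m clones
    antigen_ids: tuple[str, ...]
    clone_ids: tuple[str, ...]
    recognition: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.entries.shape
        if (n, m) != (len(self.antigen_ids), len(self.clone_ids)):
            raise ValueError("tensor shape does not match id lists")
        if np.any(self.entries[self.recognition > 0] < 0):
            raise ValueError("tensor entries must be >= 0 where recognised")


def build_allo_tensor(
    antigens: Sequence[AntigenParams],
    clones: Sequence[CloneParams],
    recognition: np.ndarray | None = None,
) -> AlloTensor:
    """Outer product of the affinity vectors masked by recognition.

    ``recognition`` is an n x m array in [0, 1] (1 = the TCR recognises the
    complex; fractional values model cross-reactivity).  Default: identity
    when n == m (one cognate antigen per clone), else an error.
    """
    n, m = len(antigens), len(clones)
    if recognition is None:
        if n != m:
            raise ValueError(
                "recognition mask required when antigen and clone counts "
                "differ")
        recognition = np.eye(n)
    recognition = np.asarray(recognition, dtype=float)
    if recognition.shape != (n, m):
        raise ValueError(
            f"recognition shape {recognition.shape} != ({n}, {m})")
    if np.any((recognition < 0) | (recognition > 1)):
        raise ValueError("recognition values must lie in [0, 1]")
    b = np.array([a.b_affinity for a in antigens])
    z = np.array([c.z_affinity for c in clones])
    return AlloTensor(
        entries=np.outer(b, z) * recognition,
        antigen_ids=tuple(a.antigen_id for a in antigens),
        clone_ids=tuple(c.clone_id for c in clones),
        recognition=recognition,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Iteration count and switches for a repertoire simulation.

    ``exponent_affinity_scale`` rescales B inside exp(-r * t * B) so the
    growth time scale can be decoupled from the affinity units; the default
    1.0 uses the affinity exactly as written.
    """

    t_max: int = 1000
    cytokine_amplification: bool = False
    exponent_affinity_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass
class Trajectory:
    """Per-clone counts N_t for t = 0..t_max plus the aggregate response."""

    times: np.ndarray                  # (t_max + 1,)
    counts: np.ndarray                 # (m clones, t_max + 1)
    clone_ids: tuple[str, ...]
    driving_antigen: dict[str, str | None] = field(default_factory=dict)

    @property
    def aggregate(self) -> np.ndarray:
        """Total repertoire response: the per-clone sum at every step."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, cid in enumerate(self.clone_ids):
            for t, n in zip(self.times, self.counts[j]):
                rows.append((int(t), cid, float(n)))
        df = pd.DataFrame(rows, columns=["t", "clone_id", "n"])
        agg = pd.DataFrame({"t": self.times.astype(int),
                            "clone_id": "AGGREGATE",
                            "n": self.aggregate})
        return pd.concat([df, agg], ignore_index=True)


def transform_repertoire(
    tensor: AlloTensor,
    antigens: Sequence[AntigenParams],
    clones: Sequence[CloneParams],
    cytokine_field: CytokineField | None = None,
    config: SimulationConfig = SimulationConfig(),
) -> Trajectory:
    """Iterate the logistic rule over every clone coupled via the tensor.

    Each clone is driven by the recognised antigen maximising B_i * Z_j
    (its strongest cognate complex); a clone recognising nothing stays flat
    at its N_0.  The clone's rate is r = CP * (S2 * Ck) with Ck = 1 when no
    cytokine field is supplied (pure signal-1 dynamics).
    """
    if len(antigens) != len(tensor.antigen_ids):
        raise ValueError("antigen list does not match tensor")
    if len(clones) != len(tensor.clone_ids):
        raise ValueError("clone list does not match tensor")
    t_max = config.t_max
    times = np.arange(t_max + 1)
    counts = np.empty((len(clones), t_max + 1))
    driving: dict[str, str | None] = {}
    for j, clone in enumerate(clones):
        col = tensor.entries[:, j]
        counts[j, 0] = clone.n0
        if not np.any(col > 0):
            counts[j, :] = clone.n0
            driving[clone.clone_id] = None
            continue
        i = int(np.argmax(col))
        antigen = antigens[i]
        driving[clone.clone_id] = antigen.antigen_id
        if cytokine_field is None:
            ck = 1.0
        else:
            ck = cytokine_net(
                cytokine_field,
                clone.receptor_levels if clone.receptor_levels else None)
        # the exponent scale rescales B inside exp(-r*t*B) only; K' keeps
        # the unscaled affinity, so fold the scale into r (they multiply)
        r = compose_r(clone.cp, clone.s2, ck) * config.exponent_affinity_scale
        n = clone.n0
        for t in range(1, t_max + 1):
            if config.cytokine_amplification:
                n = cytokine_amplified_step(n, t, antigen, clone, r, ck)
            else:
                n = logistic_step(n, t, antigen, clone, r)
            counts[j, t] = n
    return Trajectory(times=times, counts=counts,
                      clone_ids=tuple(c.clone_id for c in clones),
                      driving_antigen=driving)


@dataclass(frozen=True)
class GvhdProbabilityInputs:
    """Probabilities composing the clinical alloreactive-response risk:
    proteasomal cleavage, presentation against competing peptides, and
    presence of a responding clone in the graft."""

    p_cleave: float
    p_present: float
    p_clone: float

    def __post_init__(self) -> None:
        for name in ("p_cleave", "p_present", "p_clone"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def gvhd_probability(inputs: GvhdProbabilityInputs) -> float:
    """Product of the three probabilities; each factor below 1 diminishes
    the chance that a given peptide triggers clinical alloreactivity."""
    return inputs.p_cleave * inputs.p_present * inputs.p_clone
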