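"""Reaction-network definition of the VKBL activator–repressor gene circuit.

The circuit couples two genes: an activator A that enhances transcription of
both genes by binding their operators, and a repressor R that sequesters A
into an inert complex C.  The model tracks nine species

    D_A, D_A_bound   activator-gene operator, free / activator-occupied
    D_R, D_R_bound   repressor-gene operator, free / activator-occupied
    M_A, M_R         the two messenger RNAs
    A, R             activator and repressor proteins
    C                the A·R complex

connected by sixteen elementary mass-action reactions: reversible activator
binding at each operator, basal and activated transcription of each mRNA,
translation, complex formation, complex decay (which degrades the activator
it contains, returning R), and first-order degradation of A, R and both
mRNAs.  Degradation products are inert and are not represented as state
variables.

System size can be varied in two ways: the gene copy number ``N`` sets the
initial operator counts (``D_A = D_R = N``), and ``transMF`` multiplies the
four transcription rate constants by a common factor while leaving every
other rate untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "CircuitParameters",
    "SystemState",
    "ReactionChannel",
    "ReactionNetwork",
    "default_parameters",
    "build_network",
    "propensity",
    "read_config",
    "write_config_template",
]

#: canonical species order used by every trajectory and state array
SPECIES: tuple[str, ...] = (
    "D_A", "D_A_bound", "D_R", "D_R_bound", "M_A", "M_R", "A", "R", "C",
)

_TRANSCRIPTION_RATES = ("alpha_A", "alpha_A_prime", "alpha_R", "alpha_R_prime")


@dataclass(frozen=True)
class CircuitParameters:
    """Rate constants of the circuit, all in h⁻¹ (bimolecular ones in
    molecules⁻¹ h⁻¹), plus the two system-size controls.

    ``delta_R`` — the repressor degradation rate — is the control parameter
    of the study and has no default: it must always be given explicitly.
    """

    theta_A: float        # activator unbinding from D_A_bound
    gamma_A: float        # activator binding to D_A (molecules⁻¹ h⁻¹)
    theta_R: float        # activator unbinding from D_R_bound
    gamma_R: float        # activator binding to D_R (molecules⁻¹ h⁻¹)
    alpha_A: float        # basal transcription of M_A
    alpha_A_prime: float  # activated transcription of M_A
    alpha_R: float        # basal transcription of M_R
    alpha_R_prime: float  # activated transcription of M_R
    delta_MA: float       # M_A degradation
    delta_MR: float       # M_R degradation
    delta_A: float        # A degradation; also the complex decay rate
    beta_A: float         # translation of A
    beta_R: float         # translation of R
    gamma_C: float        # complex formation A + R (molecules⁻¹ h⁻¹)
    delta_R: float        # R degradation — control parameter
    gene_copy: int = 1    # operator copies N
    transMF: float = 1.0  # common factor on the four transcription rates

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("gene_copy", "transMF"):
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {f.name} must be finite and >= 0, got {v}")
        if not (isinstance(self.gene_copy, (int, np.integer)) and self.gene_copy >= 1):
            raise ValueError(f"gene_copy must be an integer >= 1, got {self.gene_copy}")
        if not (math.isfinite(self.transMF) and self.transMF > 0):
            raise ValueError(f"transMF must be > 0, got {self.transMF}")

    def effective_rate(self, name: str) -> float:
        """Rate constant with the transMF scaling applied where due."""
        v = getattr(self, name)
        if name in _TRANSCRIPTION_RATES:
            v *= self.transMF
        return v

    def with_(self, **kw) -> "CircuitParameters":
        return replace(self, **kw)


def default_parameters(delta_R: float, gene_copy: int = 1,
                       transMF: float = 1.0) -> CircuitParameters:
    """Standard rate constants of the circuit (the values of the original
    Vilar et al. oscillator); only ``delta_R`` must be chosen by the caller.
    """
    return CircuitParameters(
        theta_A=50.0, gamma_A=1.0, theta_R=100.0, gamma_R=1.0,
        alpha_A=50.0, alpha_A_prime=500.0, alpha_R=0.01, alpha_R_prime=50.0,
        delta_MA=10.0, delta_MR=0.5, delta_A=1.0, beta_A=50.0, beta_R=5.0,
        gamma_C=2.0, delta_R=delta_R, gene_copy=gene_copy, transMF=transMF,
    )


@dataclass
class SystemState:
    """Species counts at one instant; integer-valued for stochastic states,
    real-valued for the rate-equation model."""

    counts: np.ndarray
    time: float = 0.0
    species: tuple[str, ...] = SPECIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.species),):
            raise ValueError("counts must have one entry per species")
        if np.any(self.counts < 0):
            raise ValueError("species counts must be non-negative")

    def __getitem__(self, name: str) -> float:
        return float(self.counts[self.species.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(c) for s, c in zip(self.species, self.counts)}


@dataclass(frozen=True)
class ReactionChannel:
    """One elementary channel: at most bimolecular, mass-action kinetics.

    ``reactants`` lists the species consumed-or-catalytic that enter the
    propensity (each with multiplicity one); ``delta`` is the net change per
    firing, one entry per species in the network's species order.
    """

    label: str
    rate: float
    reactants: tuple[str, ...]
    delta: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise ValueError("channels are at most bimolecular")
        if self.rate < 0:
            raise ValueError("rate constant must be >= 0")


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    channels: tuple[ReactionChannel, ...]
    initial_counts: np.ndarray
    params: CircuitParameters | None = None

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_counts, dtype=np.int64)
        if init.shape != (len(self.species),) or np.any(init < 0):
            raise ValueError("initial_counts must be non-negative, one per species")
        object.__setattr__(self, "initial_counts", init)

    @property
    def initial_state(self) -> SystemState:
        return SystemState(self.initial_counts.astype(float), 0.0, self.species)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flat arrays consumed by the simulation kernels: rate constants,
        first/second reactant indices (−1 for none), and the stoichiometry
        matrix (n_channels × n_species)."""
        idx = {s: i for i, s in enumerate(self.species)}
        n_ch = len(self.channels)
        k = np.array([c.rate for c in self.channels], dtype=np.float64)
        r1 = np.full(n_ch, -1, dtype=np.int64)
        r2 = np.full(n_ch, -1, dtype=np.int64)
        S = np.zeros((n_ch, len(self.species)), dtype=np.int64)
        for i, c in enumerate(self.channels):
            if len(c.reactants) >= 1:
                r1[i] = idx[c.reactants[0]]
            if len(c.reactants) == 2:
                r2[i] = idx[c.reactants[1]]
            S[i, :] = c.delta
        return k, r1, r2, S


def _delta(species: Sequence[str], **changes: int) -> tuple[int, ...]:
    d = [0] * len(species)
    for name, v in changes.items():
        d[list(species).index(name)] = v
    return tuple(d)


def build_network(params: CircuitParameters) -> ReactionNetwork:
    """Assemble the sixteen reaction channels of the circuit.

    The initial state has all ``gene_copy`` operators free and every other
    count zero.  transMF multiplies exactly the four transcription channels.
    Raises ``ValueError`` via ``CircuitParameters`` validation for
    ``gene_copy`` < 1 or ``transMF`` <= 0.
    """
    p = params
    sp = SPECIES
    t = p.transMF
    ch = [
        # operator binding/unbinding; binding sequesters one A
        ReactionChannel("A binds D_A", p.gamma_A, ("D_A", "A"),
                        _delta(sp, D_A=-1, A=-1, D_A_bound=+1)),
        ReactionChannel("A unbinds D_A", p.theta_A, ("D_A_bound",),
                        _delta(sp, D_A_bound=-1, D_A=+1, A=+1)),
        ReactionChannel("A binds D_R", p.gamma_R, ("D_R", "A"),
                        _delta(sp, D_R=-1, A=-1, D_R_bound=+1)),
        ReactionChannel("A unbinds D_R", p.theta_R, ("D_R_bound",),
                        _delta(sp, D_R_bound=-1, D_R=+1, A=+1)),
        # transcription (basal from the free operator, activated from the
        # bound one); the only channels scaled by transMF
        ReactionChannel("basal transcription M_A", p.alpha_A * t, ("D_A",),
                        _delta(sp, M_A=+1)),
        ReactionChannel("activated transcription M_A", p.alpha_A_prime * t,
                        ("D_A_bound",), _delta(sp, M_A=+1)),
        ReactionChannel("basal transcription M_R", p.alpha_R * t, ("D_R",),
                        _delta(sp, M_R=+1)),
        ReactionChannel("activated transcription M_R", p.alpha_R_prime * t,
                        ("D_R_bound",), _delta(sp, M_R=+1)),
        # translation
        ReactionChannel("translation A", p.beta_A, ("M_A",), _delta(sp, A=+1)),
        ReactionChannel("translation R", p.beta_R, ("M_R",), _delta(sp, R=+1)),
        # complex formation and decay; the decaying complex releases R while
        # the activator inside it is degraded
        ReactionChannel("complex formation", p.gamma_C, ("A", "R"),
                        _delta(sp, A=-1, R=-1, C=+1)),
        ReactionChannel("complex decay (A degraded)", p.delta_A, ("C",),
                        _delta(sp, C=-1, R=+1)),
        # degradation
        ReactionChannel("A degradation", p.delta_A, ("A",), _delta(sp, A=-1)),
        ReactionChannel("R degradation", p.delta_R, ("R",), _delta(sp, R=-1)),
        ReactionChannel("M_A degradation", p.delta_MA, ("M_A",), _delta(sp, M_A=-1)),
        ReactionChannel("M_R degradation", p.delta_MR, ("M_R",), _delta(sp, M_R=-1)),
    ]
    init = np.zeros(len(sp), dtype=np.int64)
    init[sp.index("D_A")] = p.gene_copy
    init[sp.index("D_R")] = p.gene_copy
    return ReactionNetwork(sp, tuple(ch), init, params=p)


def propensity(state: SystemState | np.ndarray, channel: ReactionChannel,
               species: tuple[str, ...] = SPECIES) -> float:
    """Mass-action propensity of one channel at one state, in h⁻¹."""
    if isinstance(state, SystemState):
        counts, species = state.counts, state.species
    else:
        counts = np.asarray(state, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative species counts")
    a = channel.rate
    for r in channel.reactants:
        a *= counts[species.index(r)]
    return float(a)


# ---------------------------------------------------------------------------
# flat key: value parameter files

def write_config_template(path: str | Path, delta_R: float = 0.05) -> None:
    """Emit the default rate constants as an editable ``key: value`` file."""
    p = default_parameters(delta_R)
    lines = [
        "# VKBL circuit parameters (rates in 1/h; bimolecular in 1/molecules/h)",
        "# delta_R is the control parameter; edit freely.",
    ]
    for f in fields(p):
        lines.append(f"{f.name}: {getattr(p, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> CircuitParameters:
    kw: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition(":")
        key = key.strip()
        if key not in {f.name for f in fields(CircuitParameters)}:
            raise ValueError(f"unknown parameter {key!r} in {path}")
        kw[key] = float(val)
    if "gene_copy" in kw:
        kw["gene_copy"] = int(kw["gene_copy"])
    return CircuitParameters(**kw)  # type: ignore[arg-type]
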