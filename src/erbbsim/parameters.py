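"""Rate constants, diffusion coefficients and escape probabilities for the
ErbB2/ErbB3 membrane model.

All lengths are in micrometres, times in seconds, so diffusion coefficients
are um^2/s and a 2D association rate is um^2/s.  The tabulated dimer
on-rate is a 3D rate (um^3/s); the simulation is strictly two-dimensional,
so it is converted to a 2D rate by dividing by the thickness of the
membrane-proximal reaction layer (``reaction_depth``, default 10 nm):
``k_on_2d = k_on / reaction_depth`` = 9e-3 um^2/s.  Escape "rates" are
dimensionless per-boundary-encounter escape probabilities, not per-second
rates: a confined particle that hits a domain edge crosses it with this
probability and is otherwise reflected.

First-order events (dissociation, phosphorylation, dephosphorylation) are
converted to per-step probabilities with ``1 - exp(-k*dt)``.  The
conformational opening of unliganded ErbB3 uses a flat per-step probability
(``p_open``), deliberately not a rate conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

SPECIES = ("ErbB2", "ErbB3")

#: canonical dimer composition names
DIMER_KINDS = ("ErbB2/ErbB2", "ErbB2/ErbB3", "ErbB3/ErbB3")

#: particle kinds used by the escape table (one row per kind)
PARTICLE_KINDS = (
    "ErbB2 monomer",
    "ErbB3 monomer",
    "ErbB2/ErbB3 dimer",
    "ErbB3/ErbB3 dimer",
    "ErbB2/ErbB2 dimer",
)

#: allowed scalings of the nominal escape probability
ESCAPE_SCALINGS = (1.0, 0.5, 0.25)

#: phosphorylation site names per species
SITES = {"ErbB2": ("PY",), "ErbB3": ("PY1197", "PY1289")}


def rate_to_step_probability(k: float, dt: float) -> float:
    """Per-step event probability for a first-order rate ``k`` over ``dt``.

    Returns ``1 - exp(-k*dt)``, which lies in [0, 1) and is bounded above
    by ``k*dt``.
    """
    if k < 0:
        raise ValueError(f"rate must be non-negative, got k={k}")
    if dt < 0:
        raise ValueError(f"timestep must be non-negative, got dt={dt}")
    return -math.expm1(-k * dt)


def receptor_count_for_area(
    n_per_cell: int = 50_000,
    cell_area: float = 314.16,
    sim_area: float = 0.1995,
) -> tuple[float, int]:
    """Receptor surface density (per um^2) and the integer count for a
    simulation patch of ``sim_area``.

    50,000 receptors over a 314.16 um^2 cell gives ~159 receptors/um^2,
    which over the 0.1995 um^2 simulation space rounds down to 31 receptors
    of each species.
    """
    if n_per_cell <= 0 or cell_area <= 0 or sim_area <= 0:
        raise ValueError("receptor number and areas must be positive")
    density = n_per_cell / cell_area
    return density, int(math.floor(density * sim_area))


def _default_D_monomer() -> dict:
    return {"ErbB2": 0.0272, "ErbB3": 0.013}


def _default_D_dimer() -> dict:
    # kind -> (no site phosphorylated, any site phosphorylated)
    return {
        "ErbB2/ErbB3": (0.015, 0.0046),
        "ErbB3/ErbB3": (0.0185, 0.0028),
        "ErbB2/ErbB2": (0.015, 0.015),
    }


def _default_k_off() -> dict:
    # kind -> off rate indexed by bound-ligand count
    return {
        "ErbB2/ErbB3": (0.436, 0.408),
        "ErbB3/ErbB3": (0.436, 0.234, 0.13),
        "ErbB2/ErbB2": (4.36,),
    }


def _default_escape() -> dict:
    return {
        "ErbB2 monomer": 0.5128,
        "ErbB3 monomer": 0.2401,
        "ErbB2/ErbB3 dimer": 0.3764,
        "ErbB3/ErbB3 dimer": 0.2401,
        "ErbB2/ErbB2 dimer": 0.5128,
    }


@dataclass
class ParameterSet:
    """All model parameters.

    Defaults reproduce the published parameterisation; every field can be
    overridden, and the whole set round-trips through YAML.

    Attributes
    ----------
    D_monomer : dict
        Monomer diffusion coefficients, um^2/s.
    D_dimer : dict
        Dimer diffusion coefficients as ``kind -> (unphosphorylated,
        phosphorylated)``; the phosphorylated value applies as soon as any
        member site carries a phosphate.
    k_on : float
        Tabulated 3D dimer association rate, um^3/s, identical for all
        pairings.
    reaction_depth : float
        Thickness of the membrane-proximal reaction layer, um, used to
        convert the 3D on-rate to the 2D rate the simulation runs on
        (see :attr:`k_on_2d`).
    k_off : dict
        Dissociation rates (1/s) per composition, indexed by the number of
        ligand-bound ErbB3 members.
    k_phos, k_phos_basal : dict
        Per-site phosphorylation rates (1/s) of the activator member of a
        dimer; the full rate applies when the receiver is kinase-competent
        (ErbB2, or ErbB3 with at least one phosphorylated site), the basal
        rate otherwise.
    k_dephos : dict
        Site-specific dephosphorylation rates (1/s).
    p_open : float
        Flat per-step probability that an unliganded ErbB3 monomer is in
        the extended, dimer-competent conformation.
    escape : dict
        Nominal per-boundary-encounter escape probabilities per particle
        kind; scaled variants are derived exactly (nominal * scaling).
    dt : float
        Default timestep, s.
    unbind_factor : float
        Unbinding radius expressed as a multiple of the binding radius.
    erbb2_homodimer_on_multiplier : float
        Multiplier (in [0, 1]) on the ErbB2/ErbB2 association step.
        ErbB2 homo-interactions are disfavoured (electrostatic repulsion
        of the dimerization arms), which the model expresses as a low
        association probability on top of the 10x dissociation rate; the
        default 0.1 keeps homodimerization possible but rare.
    """

    D_monomer: dict = field(default_factory=_default_D_monomer)
    D_dimer: dict = field(default_factory=_default_D_dimer)
    k_on: float = 9e-5
    reaction_depth: float = 0.01
    k_off: dict = field(default_factory=_default_k_off)
    k_phos_basal: dict = field(
        default_factory=lambda: {"ErbB2": 0.073, "ErbB3": 0.00007}
    )
    k_phos: dict = field(default_factory=lambda: {"ErbB2": 0.146, "ErbB3": 0.078})
    k_dephos: dict = field(
        default_factory=lambda: {
            "ErbB2": {"PY": 0.2},
            "ErbB3": {"PY1197": 0.013, "PY1289": 0.06},
        }
    )
    p_open: float = 1e-4
    escape: dict = field(default_factory=_default_escape)
    dt: float = 1e-6
    unbind_factor: float = 5.0
    erbb2_homodimer_on_multiplier: float = 0.1

    def __post_init__(self):
        self.validate()

    @property
    def k_on_2d(self) -> float:
        """Effective 2D association rate, um^2/s (3D rate divided by the
        reaction-layer depth)."""
        return self.k_on / self.reaction_depth

    # -- lookups -----------------------------------------------------------

    def lookup_off_rate(self, kind: str, n_ligand: int) -> float:
        """Dissociation rate (1/s) for a dimer ``kind`` with ``n_ligand``
        ligand-bound members.

        The ligand count must be consistent with the composition: ErbB2/2
        carries no ligand, ErbB2/3 at most one, ErbB3/3 at most two.
        """
        if kind not in DIMER_KINDS:
            raise KeyError(f"unknown dimer kind {kind!r}; expected one of {DIMER_KINDS}")
        table = self.k_off[kind]
        if not 0 <= n_ligand < len(table):
            raise ValueError(
                f"ligand count {n_ligand} inconsistent with {kind} "
                f"(allowed: 0..{len(table) - 1})"
            )
        return table[n_ligand]

    def lookup_escape(self, kind: str, scaling: float = 1.0) -> float:
        """Per-encounter escape probability for a particle ``kind`` at the
        given ``scaling`` of the nominal value (1, 1/2 or 1/4).

        Scaled values are exact multiples of the nominal probability.
        """
        if kind not in PARTICLE_KINDS:
            raise KeyError(
                f"unknown particle kind {kind!r}; expected one of {PARTICLE_KINDS}"
            )
        if scaling not in ESCAPE_SCALINGS:
            raise ValueError(
                f"escape scaling must be one of {ESCAPE_SCALINGS}, got {scaling}"
            )
        return self.escape[kind] * scaling

    def mutual_diffusion(self, species_a: str, species_b: str) -> float:
        """Mutual diffusion coefficient of two monomers: the sum of their
        individual coefficients."""
        return self.D_monomer[species_a] + self.D_monomer[species_b]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for sp in SPECIES:
            if self.D_monomer[sp] < 0:
                raise ValueError(f"negative diffusion coefficient for {sp}")
        for kind in DIMER_KINDS:
            for D in self.D_dimer[kind]:
                if D < 0:
                    raise ValueError(f"negative dimer diffusion coefficient for {kind}")
            for k in self.k_off[kind]:
                if k < 0:
                    raise ValueError(f"negative off rate for {kind}")
        if self.k_on < 0:
            raise ValueError("negative association rate")
        if self.reaction_depth <= 0:
            raise ValueError("reaction_depth must be positive")
        off33 = self.k_off["ErbB3/ErbB3"]
        if any(off33[i + 1] > off33[i] for i in range(len(off33) - 1)):
            raise ValueError(
                "ErbB3/ErbB3 off rate must be non-increasing in ligand count"
            )
        for d in (self.k_phos, self.k_phos_basal):
            for sp, k in d.items():
                if k < 0:
                    raise ValueError(f"negative phosphorylation rate for {sp}")
        for sp, sites in self.k_dephos.items():
            for site, k in sites.items():
                if k < 0:
                    raise ValueError(f"negative dephosphorylation rate {sp}/{site}")
        for kind, p in self.escape.items():
            if not 0 <= p <= 1:
                raise ValueError(f"escape probability for {kind} outside [0, 1]")
        if not 0 <= self.p_open <= 1:
            raise ValueError("p_open outside [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.unbind_factor <= 0:
            raise ValueError("unbind_factor must be positive")
        if not 0 <= self.erbb2_homodimer_on_multiplier <= 1:
            raise ValueError("erbb2_homodimer_on_multiplier outside [0, 1]")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        """Serialize to a human-editable YAML key tree; optionally write it."""
        doc = asdict(self)
        # tuples -> lists for clean YAML
        doc["D_dimer"] = {k: list(v) for k, v in doc["D_dimer"].items()}
        doc["k_off"] = {k: list(v) for k, v in doc["k_off"].items()}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ParameterSet":
        """Load a ParameterSet from a YAML file path or YAML string.

        Missing keys fall back to the defaults; unknown keys are rejected.
        """
        p = Path(source) if not str(source).lstrip().startswith(("{", "D_", "k_")) else None
        if p is not None and p.exists():
            doc = yaml.safe_load(p.read_text())
        else:
            doc = yaml.safe_load(str(source))
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError("parameter file must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if "D_dimer" in doc:
            doc["D_dimer"] = {k: tuple(v) for k, v in doc["D_dimer"].items()}
        if "k_off" in doc:
            doc["k_off"] = {k: tuple(v) for k, v in doc["k_off"].items()}
        return cls(**doc)
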