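"""Monoisotopic mass bookkeeping for middle-down photolabeling analysis.

Residues, fixed/variable modifications, photoreagent adducts, peptides with
positioned modifications, charge-state arithmetic and in-silico tryptic
digestion.  All masses are monoisotopic daltons; ions are positive-mode
[M+zH]z+ throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "ResidueMassTable",
    "ModificationSpec",
    "AdductSpec",
    "Peptide",
    "ModifiedPeptide",
    "DigestParams",
    "default_mass_table",
    "default_modifications",
    "default_adducts",
    "peptide_mass",
    "mz_from_mass",
    "mass_from_mz",
    "digest",
    "ppm_error",
    "read_fasta",
]


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic masses of the 20 standard residues plus water and proton."""

    residues: dict[str, float]
    water: float
    proton: float

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residues)
        if missing:
            raise ValueError(f"residue table missing standard residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residues.values()):
            raise ValueError("residue masses must be strictly positive")
        if abs(self.water - 18.01056) > 1e-4:
            raise ValueError(f"water mass {self.water} outside expected range")
        if abs(self.proton - 1.00728) > 1e-4:
            raise ValueError(f"proton mass {self.proton} outside expected range")

    def mass(self, residue: str, position: int | None = None) -> float:
        try:
            return self.residues[residue]
        except KeyError:
            where = "" if position is None else f" at position {position}"
            raise KeyError(f"unknown residue letter {residue!r}{where}") from None


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable modification: a mass delta with residue specificity."""

    name: str
    delta_mass: float
    specificity: frozenset[str] | str = "any"  # residue letters, or "any"
    mod_class: str = "variable"

    def __post_init__(self) -> None:
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < float("inf")):
            raise ValueError(f"modification {self.name}: delta_mass must be finite")
        if self.specificity != "any" and not self.specificity:
            raise ValueError(f"modification {self.name}: empty specificity")


@dataclass(frozen=True)
class AdductSpec:
    """A photoreagent adduct, optionally click-tagged with a heavy/light isotope pair.

    ``pair_delta`` is the MS1 doublet spacing produced by mixed heavy/light
    tagging; when both tag masses are given it must equal their difference
    unless explicitly overridden (some instruments' nominal spacings are
    printed at lower precision than the tag masses themselves).
    """

    reagent: str
    adduct_mass: float
    light_tag_mass: float | None = None
    heavy_tag_mass: float | None = None
    pair_delta: float | None = None
    allow_pair_delta_override: bool = False

    def __post_init__(self) -> None:
        if self.adduct_mass <= 0:
            raise ValueError(f"adduct {self.reagent}: adduct_mass must be > 0")
        if self.light_tag_mass is not None and self.heavy_tag_mass is not None:
            implied = self.heavy_tag_mass - self.light_tag_mass
            if self.pair_delta is None:
                object.__setattr__(self, "pair_delta", implied)
            elif abs(self.pair_delta - implied) > 1e-6 and not self.allow_pair_delta_override:
                raise ValueError(
                    f"adduct {self.reagent}: pair_delta {self.pair_delta} inconsistent "
                    f"with tag masses (implied {implied}); set allow_pair_delta_override"
                )

    @property
    def delta_mass(self) -> float:
        """Alias so an adduct can sit wherever a modification is expected."""
        return self.adduct_mass

    @property
    def name(self) -> str:
        return self.reagent


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide in 1-based inclusive protein coordinates."""

    sequence: str
    protein_id: str = ""
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}-{self.end} inconsistent with length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def to_protein(self, local_pos: int) -> int:
        """Convert a 1-based within-peptide index to protein coordinates."""
        if not 1 <= local_pos <= len(self):
            raise ValueError(f"position {local_pos} outside 1..{len(self)}")
        return self.start + local_pos - 1


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide plus positioned modifications; at most one photoreagent adduct."""

    peptide: Peptide
    modifications: tuple[tuple[int, ModificationSpec | AdductSpec], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "modifications", tuple(self.modifications))
        n = len(self.peptide)
        for pos, _mod in self.modifications:
            if not 1 <= pos <= n:
                raise ValueError(f"modification position {pos} outside 1..{n}")
        if sum(isinstance(m, AdductSpec) for _p, m in self.modifications) > 1:
            raise ValueError("at most one photoreagent adduct per peptide")

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def adduct_placement(self) -> tuple[int, AdductSpec] | None:
        for pos, mod in self.modifications:
            if isinstance(mod, AdductSpec):
                return pos, mod
        return None


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 3
    min_length: int = 1
    max_length: int = 100

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")


def default_mass_table() -> ResidueMassTable:
    """Load the shipped 5-decimal residue table."""
    raw = json.loads(
        resources.files("photosite").joinpath("data/residue_masses.json").read_text()
    )
    return ResidueMassTable(raw["residues"], raw["water"], raw["proton"])


# Registry defaults.  Reagent adduct masses follow the variable-modification
# masses used for the search (KK123 372.16, KK200 462.27, KK202 500.31,
# FLI-tagged KK123 672.4322 light / 682.44 heavy); the heavy-light doublet
# spacing defaults to the tag-mass difference (10.0078), with the nominal
# 10.07 spacing available as an override.  The NEM+DTT mass is a convention
# (sum of the NEM and DTT monoisotopic additions); override via config.
def default_modifications() -> dict[str, ModificationSpec]:
    return {
        m.name: m
        for m in (
            ModificationSpec("Oxidation(M)", 15.99491, frozenset("M")),
            ModificationSpec("NEM(C)", 125.04768, frozenset("C")),
            ModificationSpec("NEM+DTT(C)", 279.05994, frozenset("C")),
        )
    }


def default_adducts(nominal_pair_delta: bool = False) -> dict[str, AdductSpec]:
    fli = dict(light_tag_mass=672.4322, heavy_tag_mass=682.44)
    if nominal_pair_delta:
        fli.update(pair_delta=10.07, allow_pair_delta_override=True)
    return {
        a.reagent: a
        for a in (
            AdductSpec("KK123", 372.16),
            AdductSpec("KK200", 462.27),
            AdductSpec("KK202", 500.31),
            AdductSpec("KK123-FLI-light", 672.4322, **fli),
            AdductSpec("KK123-FLI-heavy", 682.44, **fli),
        )
    }


def peptide_mass(
    p: ModifiedPeptide | Peptide | str, table: ResidueMassTable | None = None
) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    table = table or default_mass_table()
    if isinstance(p, str):
        p = ModifiedPeptide(Peptide(p))
    elif isinstance(p, Peptide):
        p = ModifiedPeptide(p)
    total = table.water
    for i, residue in enumerate(p.sequence, start=1):
        total += table.mass(residue, i)
    for _pos, mod in p.modifications:
        total += mod.delta_mass
    return total


def mz_from_mass(neutral_mass: float, z: int, table: ResidueMassTable | None = None) -> float:
    """[M+zH]z+ m/z of a neutral mass."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    proton = (table or default_mass_table()).proton
    return (neutral_mass + z * proton) / z


def mass_from_mz(mz: float, z: int, table: ResidueMassTable | None = None) -> float:
    """Neutral mass from an [M+zH]z+ m/z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    proton = (table or default_mass_table()).proton
    return z * mz - z * proton


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


def _tryptic_sites(sequence: str) -> list[int]:
    """0-based indices i such that cleavage occurs between i and i+1.

    Trypsin: C-terminal to K or R, except when the next residue is P.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    params: DigestParams | None = None,
    protein_id: str = "",
) -> list[Peptide]:
    """All tryptic peptides with up to ``max_missed_cleavages`` internal missed sites."""
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    params = params or DigestParams()
    sites = _tryptic_sites(protein_sequence)
    # fragment boundaries as 0-based half-open [a, b)
    bounds = [0] + [s + 1 for s in sites] + [len(protein_sequence)]
    pieces = list(zip(bounds[:-1], bounds[1:]))
    out: list[Peptide] = []
    for i in range(len(pieces)):
        for k in range(params.max_missed_cleavages + 1):
            j = i + k
            if j >= len(pieces):
                break
            a, b = pieces[i][0], pieces[j][1]
            if not params.min_length <= b - a <= params.max_length:
                continue
            out.append(
                Peptide(
                    protein_sequence[a:b],
                    protein_id=protein_id,
                    start=a + 1,
                    end=b,
                    missed_cleavages=k,
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def read_fasta(path) -> dict[str, str]:
    """Read subunit sequences; record id (first token of header) -> sequence."""
    from pyteomics import fasta

    out: dict[str, str] = {}
    with fasta.read(str(path)) as reader:
        for entry in reader:
            out[entry.description.split()[0]] = entry.sequence
    return out


def load_chemistry_config(config: dict) -> tuple[
    ResidueMassTable, dict[str, ModificationSpec], dict[str, AdductSpec]
]:
    """Apply a JSON config section ``chemistry`` over the shipped defaults.

    Recognised keys: ``residues`` (letter -> mass overrides), ``water``,
    ``proton``, ``modifications`` (name -> {delta_mass, specificity, class}),
    ``adducts`` (name -> {adduct_mass, light_tag_mass, heavy_tag_mass,
    pair_delta}).
    """
    section = config.get("chemistry", {})
    base = default_mass_table()
    residues = dict(base.residues)
    residues.update(section.get("residues", {}))
    table = ResidueMassTable(
        residues, section.get("water", base.water), section.get("proton", base.proton)
    )
    mods = default_modifications()
    for name, spec in section.get("modifications", {}).items():
        spec_set = spec.get("specificity", "any")
        if spec_set != "any":
            spec_set = frozenset(spec_set)
        mods[name] = ModificationSpec(
            name, spec["delta_mass"], spec_set, spec.get("class", "variable")
        )
    adducts = default_adducts()
    for name, spec in section.get("adducts", {}).items():
        adducts[name] = AdductSpec(
            name,
            spec["adduct_mass"],
            spec.get("light_tag_mass"),
            spec.get("heavy_tag_mass"),
            spec.get("pair_delta"),
            allow_pair_delta_override="pair_delta" in spec,
        )
    return table, mods, adducts
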