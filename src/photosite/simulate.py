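"""Ground-truth synthetic LC-MS/MS generator (plus small ephys tables).

Emulates the structure of a middle-down photolabeling experiment so the
whole pipeline is testable without external data: unlabeled peptide
features elute as Gaussian profiles; their photolabeled forms appear at
the adduct-shifted mass with a configured area ratio (the labeling
efficiency) and a delayed retention apex; click-tagged species appear as
co-eluting heavy/light MS1 doublets at a fixed neutral-mass offset; MS2
spectra at the labeled apex contain each b/y ladder ion with a configured
completeness probability, neutral-loss duplicates of adduct-bearing ions,
and uniform noise peaks.  Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chem import (
    AdductSpec,
    ModifiedPeptide,
    Peptide,
    ResidueMassTable,
    default_adducts,
    default_mass_table,
    mz_from_mass,
    peptide_mass,
)
from .io import MS2Spectrum, PeakList, Run
from .localize import theoretical_ladder

__all__ = [
    "SpeciesConfig",
    "SyntheticRunConfig",
    "GroundTruth",
    "generate_run",
    "generate_ms2",
    "EphysGroupConfig",
    "generate_ephys_table",
]


@dataclass
class SpeciesConfig:
    """One peptide/adduct species to inject into the synthetic run."""

    peptide: Peptide
    adduct: AdductSpec
    true_site: int  # 1-based within-peptide index
    efficiency_pct: float = 1.0
    unlabeled_rt: float = 70.0  # min
    rt_shift: float = 10.0  # labeled apex = unlabeled apex + shift
    charges: tuple[int, ...] = (4,)
    amplitude: float = 1.0e6  # unlabeled apex intensity
    paired: bool = False  # emit heavy/light doublet (adduct needs pair_delta)
    fixed_mods: tuple = ()  # (position, ModificationSpec) pairs

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency_pct <= 100.0:
            raise ValueError("efficiency_pct must lie in [0, 100]")
        if not 1 <= self.true_site <= len(self.peptide):
            raise ValueError("true_site outside peptide")
        if self.paired and self.adduct.pair_delta is None:
            raise ValueError(f"paired species needs pair_delta on adduct {self.adduct.reagent}")


@dataclass
class SyntheticRunConfig:
    species: list[SpeciesConfig]
    sigma_min: float = 0.2  # Gaussian elution sigma, min
    scan_interval_min: float = 0.05  # MS1 cadence (3 s survey cycle)
    rt_range: tuple[float, float] | None = None  # derived from species if None
    ladder_completeness: float = 0.8
    neutral_loss_fraction: float = 0.3
    noise_peaks: int = 10
    noise_mz_range: tuple[float, float] = (100.0, 2000.0)
    mixing_ratio: float = 1.0  # light:heavy for paired species
    fragment_base_intensity: float = 1.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be > 0")
        if not 0.0 <= self.ladder_completeness <= 1.0:
            raise ValueError("ladder_completeness must lie in [0, 1]")
        if not 0.0 <= self.neutral_loss_fraction <= 1.0:
            raise ValueError("neutral_loss_fraction must lie in [0, 1]")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")
        if not self.species:
            raise ValueError("at least one species required")


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    species: list[dict] = field(default_factory=list)

    def for_peptide(self, sequence: str) -> dict:
        for entry in self.species:
            if entry["sequence"] == sequence:
                return entry
        raise KeyError(sequence)


def _modified(sp: SpeciesConfig) -> ModifiedPeptide:
    mods = tuple(sp.fixed_mods) + ((sp.true_site, sp.adduct),)
    return ModifiedPeptide(sp.peptide, mods)


def generate_ms2(
    sp: SpeciesConfig,
    cfg: SyntheticRunConfig,
    rng: np.random.Generator,
    charge: int,
    precursor_mz: float,
    rt: float,
    heavy: bool = False,
    table: ResidueMassTable | None = None,
) -> tuple[MS2Spectrum, list[dict]]:
    """One MS2 spectrum for a labeled species; returns (spectrum, truth fragments)."""
    table = table or default_mass_table()
    frag_charges = tuple(range(1, min(max(charge - 1, 1), 3) + 1))
    ladder = theoretical_ladder(
        ModifiedPeptide(sp.peptide, tuple(sp.fixed_mods)),
        sp.true_site,
        charges=frag_charges,
        include_neutral_loss=False,
        adduct=sp.adduct,
        table=table,
    )
    pairs: list[tuple[float, float]] = []
    truth: list[dict] = []
    base = cfg.fragment_base_intensity
    shift = (sp.adduct.pair_delta or 0.0) if heavy else 0.0
    for ion in ladder:
        if rng.random() >= cfg.ladder_completeness:
            continue
        mz = ion.mz + (shift / ion.charge if ion.carries_adduct else 0.0)
        inten = base * rng.uniform(0.2, 1.0)
        pairs.append((mz, inten))
        truth.append(
            {
                "series": ion.series, "index": ion.index, "charge": ion.charge,
                "carries_adduct": ion.carries_adduct, "neutral_loss": False, "mz": mz,
            }
        )
        if ion.carries_adduct and rng.random() < cfg.neutral_loss_fraction:
            nl_mz = mz - (sp.adduct.adduct_mass + shift) / ion.charge
            nl_inten = base * rng.uniform(0.1, 0.5)
            pairs.append((nl_mz, nl_inten))
            truth.append(
                {
                    "series": ion.series, "index": ion.index, "charge": ion.charge,
                    "carries_adduct": False, "neutral_loss": True, "mz": nl_mz,
                }
            )
    base_peak = max((i for _m, i in pairs), default=base)
    lo, hi = cfg.noise_mz_range
    for _ in range(cfg.noise_peaks):
        noise_mz = rng.uniform(lo, hi)
        noise_int = base_peak * 10.0 ** rng.uniform(-3.0, 0.0)
        pairs.append((noise_mz, noise_int))
    spectrum = MS2Spectrum(
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        rt=rt,
        peaks=PeakList.from_pairs(pairs),
    )
    return spectrum, truth


def generate_run(
    cfg: SyntheticRunConfig, table: ResidueMassTable | None = None
) -> tuple[Run, GroundTruth]:
    """Emit a full synthetic run plus its ground truth."""
    table = table or default_mass_table()
    rng = np.random.default_rng(cfg.seed)
    if cfg.rt_range is None:
        lo = min(sp.unlabeled_rt for sp in cfg.species) - 6 * cfg.sigma_min
        hi = max(sp.unlabeled_rt + sp.rt_shift for sp in cfg.species) + 6 * cfg.sigma_min
    else:
        lo, hi = cfg.rt_range
    n_scans = int(round((hi - lo) / cfg.scan_interval_min)) + 1
    grid = lo + cfg.scan_interval_min * np.arange(n_scans)

    # per-species m/z bookkeeping
    truth = GroundTruth()
    elution: list[tuple[float, float, float]] = []  # (mz, apex_rt, amplitude)
    for sp in cfg.species:
        base_mass = peptide_mass(ModifiedPeptide(sp.peptide, tuple(sp.fixed_mods)), table)
        labeled_mass = base_mass + sp.adduct.adduct_mass
        labeled_rt = sp.unlabeled_rt + sp.rt_shift
        labeled_amp = sp.amplitude * sp.efficiency_pct / 100.0
        entry = {
            "sequence": sp.peptide.sequence,
            "protein_id": sp.peptide.protein_id,
            "true_site_local": sp.true_site,
            "true_site_protein": sp.peptide.to_protein(sp.true_site),
            "efficiency_pct": sp.efficiency_pct,
            "unlabeled_rt": sp.unlabeled_rt,
            "labeled_rt": labeled_rt,
            "charges": list(sp.charges),
            "unlabeled_mz": {}, "labeled_mz": {},
            "paired": sp.paired, "pairs": [], "fragments": [],
        }
        for z in sp.charges:
            u_mz = mz_from_mass(base_mass, z, table)
            l_mz = mz_from_mass(labeled_mass, z, table)
            entry["unlabeled_mz"][z] = u_mz
            entry["labeled_mz"][z] = l_mz
            elution.append((u_mz, sp.unlabeled_rt, sp.amplitude))
            if sp.paired:
                ratio = cfg.mixing_ratio
                light_amp = labeled_amp * ratio / (1.0 + ratio)
                heavy_amp = labeled_amp * 1.0 / (1.0 + ratio)
                h_mz = l_mz + sp.adduct.pair_delta / z
                elution.append((l_mz, labeled_rt, light_amp))
                elution.append((h_mz, labeled_rt, heavy_amp))
                entry["pairs"].append(
                    {"charge": z, "light_mz": l_mz, "heavy_mz": h_mz,
                     "pair_delta": sp.adduct.pair_delta}
                )
            else:
                elution.append((l_mz, labeled_rt, labeled_amp))
        truth.species.append(entry)

    ms1: list[tuple[float, PeakList]] = []
    for t in grid:
        pairs = []
        for mz, apex, amp in elution:
            inten = amp * np.exp(-0.5 * ((t - apex) / cfg.sigma_min) ** 2)
            if inten >= 1e-3:
                pairs.append((mz, inten))
        ms1.append((float(t), PeakList.from_pairs(pairs)))

    ms2: list[MS2Spectrum] = []
    for sp, entry in zip(cfg.species, truth.species):
        if sp.efficiency_pct <= 0:
            continue
        z = sp.charges[0]
        labeled_rt = entry["labeled_rt"]
        spectrum, frags = generate_ms2(
            sp, cfg, rng, z, entry["labeled_mz"][z], labeled_rt, heavy=False, table=table
        )
        ms2.append(spectrum)
        entry["fragments"].append({"form": "light", "ions": frags})
        if sp.paired:
            h_mz = entry["labeled_mz"][z] + sp.adduct.pair_delta / z
            spectrum_h, frags_h = generate_ms2(
                sp, cfg, rng, z, h_mz, labeled_rt, heavy=True, table=table
            )
            ms2.append(spectrum_h)
            entry["fragments"].append({"form": "heavy", "ions": frags_h})

    run = Run(ms1, ms2, {"generator_seed": cfg.seed})
    return run, truth


# ---------------------------------------------------------------------------
# Electrophysiology tables


@dataclass
class EphysGroupConfig:
    """Per-construct effect sizes for the synthetic peak-current table.

    Currents are signed as recorded at a -60 mV holding potential: GABA-
    elicited responses are inward (negative), the picrotoxin shift of the
    holding current is positive.  ``potentiation`` is the GABA+modulator /
    GABA peak-response ratio; ``direct_activation`` is the modulator-alone
    response as a fraction of the saturating GABA + propofol response;
    ``po_const`` is the constitutive open probability.
    """

    construct: str = "wt"
    n: int = 7
    potentiation: tuple[float, float] = (9.7, 4.7)  # mean, SD of the ratio
    direct_activation: tuple[float, float] = (0.034, 0.012)  # fraction of max
    po_const: tuple[float, float] = (0.01, 0.005)
    gaba_current_uA: tuple[float, float] = (1.0, 0.3)  # magnitude
    max_current_uA: tuple[float, float] = (10.0, 2.0)  # saturating GABA+propofol magnitude

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("potentiation", "direct_activation", "po_const",
                     "gaba_current_uA", "max_current_uA"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name}: SD must be >= 0")


def _truncated_normal(rng, mean, sd, size):
    """Normal draws truncated at 0 (degenerate when sd == 0)."""
    draws = rng.normal(mean, sd, size) if sd > 0 else np.full(size, float(mean))
    return np.clip(draws, 0.0, None)


def generate_ephys_table(
    groups: list[EphysGroupConfig] | EphysGroupConfig, seed: int = 0
) -> pd.DataFrame:
    """Per-cell peak-current table (one row per cell, signed currents)."""
    if isinstance(groups, EphysGroupConfig):
        groups = [groups]
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        gaba = _truncated_normal(rng, *g.gaba_current_uA, g.n)
        ratio = _truncated_normal(rng, *g.potentiation, g.n)
        frac = _truncated_normal(rng, *g.direct_activation, g.n)
        po = np.clip(_truncated_normal(rng, *g.po_const, g.n), 0.0, 0.99)
        mx = _truncated_normal(rng, *g.max_current_uA, g.n)
        for i in range(g.n):
            rows.append(
                {
                    "cell_id": f"{g.construct}-{i + 1}",
                    "construct": g.construct,
                    "i_gaba": -gaba[i],
                    "i_gaba_mod": -gaba[i] * ratio[i],
                    "i_mod_alone": -frac[i] * mx[i],
                    "i_picrotoxin": mx[i] * po[i] / (1.0 - po[i]),
                    "i_gaba_sat_propofol": -mx[i],
                }
            )
    return pd.DataFrame(rows)
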