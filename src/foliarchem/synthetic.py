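"""Synthetic study generator: spectra, feature tables, and metadata.

Emulates the statistical structure of a comparative foliar-metabolome study:
a library of ~1,300 compounds organised into structural classes (compounds
of one class share most fragment peaks, so they connect in the molecular
network; singletons share none), sampled into species compound pools with
strong species-level turnover, weaker ontogenetic (leaf-age) turnover, and a
small inducible fraction whose intensities respond multiplicatively to
hormone treatment.  Intensity noise is lognormal, matching the
multiplicative error of MS ion counts.

The default :func:`default_study_design` reproduces the study shape: four
focal species (one per genus) sampled over {young, mature} x {treatment,
control} for 57 samples total, plus 45 congeneric species contributing one
young control sample each — 102 leaf samples — and blank extractions
carrying designated laboratory contaminants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .spectra import Spectrum, write_mgf

__all__ = [
    "EffectConfig",
    "StudyDesign",
    "LibraryCompound",
    "CompoundLibrary",
    "default_effect_config",
    "default_study_design",
    "generate_compound_library",
    "simulate_spectra",
    "simulate_feature_table",
    "generate_study_fixture",
]

PROTON = 1.00728  # Da, [M+H]+ surrogate
MZ_LO, MZ_HI = 50.0, 1600.0

_CELLS = (("young", "control"), ("young", "JA"), ("mature", "control"), ("mature", "JA"))


@dataclass(frozen=True)
class EffectConfig:
    """Effect sizes and library shape for the generator.

    Proportions live in [0, 1]; counts are >= 1.  ``species_compound_overlap``
    is the expected fraction of its compounds a species shares with a
    congener (implemented exactly, as a shared genus core);
    ``age_turnover`` is the fraction of a species' compounds exclusive to one
    leaf age; treated samples multiply inducible compounds by
    ``induction_fold``.  ``noise_sigma`` is the SD of log-intensities.
    """

    n_classes: int = 67
    compounds_per_class: int = 12
    singleton_fraction: float = 498 / 1302
    template_peaks_per_class: int = 20
    peaks_per_compound: int = 25
    shared_peak_fraction: float = 0.8
    species_compound_overlap: float = 0.15
    age_turnover: float = 0.30
    inducible_fraction: float = 0.10
    induction_fold: float = 2.0
    noise_sigma: float = 0.6
    seed: int = 0
    compounds_per_species: int = 70
    n_contaminants: int = 3

    def __post_init__(self) -> None:
        for name in ("singleton_fraction", "shared_peak_fraction",
                     "species_compound_overlap", "age_turnover", "inducible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_classes", "compounds_per_class", "template_peaks_per_class",
                     "peaks_per_compound", "compounds_per_species"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v}")
        if self.n_contaminants < 0:
            raise ConfigurationError(f"n_contaminants must be >= 0, got {self.n_contaminants}")
        if self.induction_fold < 1.0:
            raise ConfigurationError(f"induction_fold must be >= 1, got {self.induction_fold}")
        if self.noise_sigma < 0.0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: genera with congener counts, one focal species each.

    ``cell_counts`` optionally fixes per-cell sample counts for a focal
    species as four integers ordered (young control, young JA, mature
    control, mature JA); species not listed use ``replicates_per_cell``.
    """

    genera: dict[str, int]
    focal_species: dict[str, str]
    replicates_per_cell: int = 3
    include_blanks: int = 3
    cell_counts: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ConfigurationError("replicates_per_cell must be >= 1")
        if self.include_blanks < 0:
            raise ConfigurationError("include_blanks must be >= 0")
        if set(self.focal_species) != set(self.genera):
            raise ConfigurationError(
                "focal_species must name exactly one species per genus in `genera`")
        focal_names = list(self.focal_species.values())
        if len(set(focal_names)) != len(focal_names):
            raise ConfigurationError("focal species names must be distinct across genera")
        for sp in self.cell_counts:
            if sp not in focal_names:
                raise ConfigurationError(f"cell_counts references unknown focal species {sp!r}")

    def focal_cells(self, species: str) -> tuple[int, ...]:
        return tuple(self.cell_counts.get(species, (self.replicates_per_cell,) * 4))

    @property
    def n_leaf_samples(self) -> int:
        focal = sum(sum(self.focal_cells(sp)) for sp in self.focal_species.values())
        return focal + sum(self.genera.values())


def default_effect_config(**overrides) -> EffectConfig:
    """Default effect configuration: 1,302 compounds (67 classes x 12 + 498
    singletons), species turnover >> ontogenetic turnover >> induction."""
    return EffectConfig(**overrides)


def default_study_design() -> StudyDesign:
    """The 102-leaf-sample design: 4 focal species x 2 ages x 2 treatments
    (57 samples via uneven cells) plus 45 single-sample congeners."""
    genera = {"Inga": 14, "Piper": 10, "Protium": 2, "Psychotria": 19}
    focal = {"Inga": "Inga_focalis", "Piper": "Piper_focalis",
             "Protium": "Protium_focalis", "Psychotria": "Psychotria_focalis"}
    cells = {"Inga_focalis": (4, 4, 4, 3),
             "Piper_focalis": (4, 4, 3, 3),
             "Protium_focalis": (4, 4, 3, 3),
             "Psychotria_focalis": (4, 4, 3, 3)}
    return StudyDesign(genera=genera, focal_species=focal, replicates_per_cell=3,
                       include_blanks=3, cell_counts=cells)


@dataclass(frozen=True)
class LibraryCompound:
    """Latent library entry: class id (None for singletons) plus the true
    fragment template the compound's spectra are generated from."""

    id: str
    class_id: int | None
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float

    def spectrum(self, sid: str | None = None) -> Spectrum:
        return Spectrum(id=sid or self.id, precursor_mz=self.precursor_mz,
                        mz=self.mz.copy(), intensity=self.intensity.copy())


@dataclass(frozen=True)
class CompoundLibrary:
    compounds: tuple[LibraryCompound, ...]
    config: EffectConfig

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def __getitem__(self, cid: str) -> LibraryCompound:
        return self._index()[cid]

    def _index(self) -> dict[str, LibraryCompound]:
        return {c.id: c for c in self.compounds}

    def __len__(self) -> int:
        return len(self.compounds)


def _class_sizes(cfg: EffectConfig) -> tuple[int, int]:
    n_class_compounds = cfg.n_classes * cfg.compounds_per_class
    if cfg.singleton_fraction >= 1.0:
        raise ConfigurationError("singleton_fraction must be < 1 to generate a library")
    n_singletons = round(n_class_compounds * cfg.singleton_fraction
                         / (1.0 - cfg.singleton_fraction))
    return n_class_compounds, n_singletons


def generate_compound_library(cfg: EffectConfig) -> CompoundLibrary:
    """Generate the latent compound library.

    Compounds of one class draw ``shared_peak_fraction`` of their peaks
    (positions and, up to lognormal jitter, intensities) from the class
    template, so same-class spectral cosines are high; singleton compounds
    use only fresh random peaks and so share no template peak with any
    class.  Fragment m/z are uniform on [50, 1600] Da and the precursor is
    the heaviest fragment plus one proton mass.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    n_class_compounds, n_singletons = _class_sizes(cfg)
    n_shared = min(round(cfg.shared_peak_fraction * cfg.peaks_per_compound),
                   cfg.template_peaks_per_class)
    compounds: list[LibraryCompound] = []

    def _build(cid: str, class_id: int | None, tmpl_mz, tmpl_int) -> LibraryCompound:
        if class_id is not None and n_shared > 0:
            pick = rng.choice(tmpl_mz.size, size=n_shared, replace=False)
            mz = tmpl_mz[pick]
            it = tmpl_int[pick] * rng.lognormal(0.0, 0.3, size=n_shared)
        else:
            mz = np.empty(0)
            it = np.empty(0)
        n_unique = cfg.peaks_per_compound - mz.size
        mz = np.concatenate([mz, rng.uniform(MZ_LO, MZ_HI, size=n_unique)])
        it = np.concatenate([it, rng.lognormal(0.0, 1.0, size=n_unique)])
        order = np.argsort(mz)
        mz, it = mz[order], it[order]
        return LibraryCompound(id=cid, class_id=class_id, mz=mz, intensity=it,
                               precursor_mz=float(mz[-1]) + PROTON)

    k = 0
    for c in range(cfg.n_classes):
        tmpl_mz = np.sort(rng.uniform(MZ_LO, MZ_HI, size=cfg.template_peaks_per_class))
        tmpl_int = rng.lognormal(0.0, 1.0, size=cfg.template_peaks_per_class)
        for _ in range(cfg.compounds_per_class):
            compounds.append(_build(f"M{k:05d}", c, tmpl_mz, tmpl_int))
            k += 1
    for _ in range(n_singletons):
        compounds.append(_build(f"M{k:05d}", None, None, None))
        k += 1
    return CompoundLibrary(compounds=tuple(compounds), config=cfg)


def simulate_spectra(library: CompoundLibrary | Sequence[LibraryCompound],
                     n_replicates_per_compound: int = 3, mz_jitter: float = 0.005,
                     intensity_cv: float = 0.2, seed: int | None = None) -> list[Spectrum]:
    """Replicate spectra per library compound with m/z and intensity noise.

    Fragment m/z are perturbed uniformly within +-``mz_jitter``/2 (so two
    replicates differ by at most ``mz_jitter``, matchable at that tolerance)
    and intensities multiplied by lognormal noise with sigma
    ``intensity_cv``.  Spectrum ids are ``<compound_id>.<replicate>``; the
    prefix is the feature-id contract carried into the MGF TITLE.
    """
    if n_replicates_per_compound < 1:
        raise ConfigurationError("n_replicates_per_compound must be >= 1")
    if mz_jitter < 0:
        raise ConfigurationError(f"mz_jitter must be >= 0, got {mz_jitter}")
    if intensity_cv < 0:
        raise ConfigurationError(f"intensity_cv must be >= 0, got {intensity_cv}")
    comps = library.compounds if isinstance(library, CompoundLibrary) else library
    rng = np.random.default_rng(seed)
    out: list[Spectrum] = []
    for comp in comps:
        for r in range(n_replicates_per_compound):
            mz = comp.mz + rng.uniform(-mz_jitter / 2, mz_jitter / 2, size=comp.mz.size)
            it = comp.intensity * np.exp(rng.normal(0.0, intensity_cv, size=comp.mz.size))
            order = np.argsort(mz)
            out.append(Spectrum(id=f"{comp.id}.{r + 1}",
                                precursor_mz=comp.precursor_mz,
                                mz=mz[order], intensity=it[order]))
    return out


def _species_table(design: StudyDesign) -> list[tuple[str, str, bool]]:
    """(species, genus, is_focal) rows, focal first within each genus."""
    rows = []
    for genus in design.genera:
        rows.append((design.focal_species[genus], genus, True))
        for j in range(design.genera[genus]):
            rows.append((f"{genus}_sp{j + 1:02d}", genus, False))
    return rows


def simulate_feature_table(design: StudyDesign, cfg: EffectConfig
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the samples x compounds intensity table plus metadata.

    Species compound pools are built per genus as a shared core of
    ``round(species_compound_overlap * compounds_per_species)`` compounds
    plus per-species unique compounds drawn disjointly within the genus, so
    two congeners share exactly the core.  Within a species,
    ``age_turnover`` of the pool is split between young-only and mature-only
    expression; treated samples multiply the species' inducible compounds by
    ``induction_fold``.  Intensities are lognormal around per-compound base
    abundances (log-uniform over 3 decades).  Blank samples contain only the
    designated contaminant compounds.

    Returns ``(table, metadata, truth)`` where ``truth`` records the latent
    classes, pools, splits and effect assignments.
    """
    library = generate_compound_library(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    all_ids = np.array(library.ids)
    k = cfg.compounds_per_species
    core_n = round(cfg.species_compound_overlap * k)

    species_rows = _species_table(design)
    pools: dict[str, list[str]] = {}
    used: set[str] = set()
    for genus in design.genera:
        sp_in_genus = [s for s, g, _ in species_rows if g == genus]
        need = core_n + len(sp_in_genus) * (k - core_n)
        if need > len(all_ids):
            raise ConfigurationError(
                f"genera[{genus!r}]: needs {need} distinct compounds for "
                f"{len(sp_in_genus)} species but the library holds {len(all_ids)}; "
                "reduce compounds_per_species or congener count")
        draw = rng.choice(all_ids, size=need, replace=False)
        core = list(draw[:core_n])
        rest = draw[core_n:]
        for i, sp in enumerate(sp_in_genus):
            uniq = list(rest[i * (k - core_n):(i + 1) * (k - core_n)])
            pools[sp] = sorted(core + uniq)
        used.update(draw)

    # ontogenetic split and inducible set, per species
    n_age = round(cfg.age_turnover * k)
    n_ind = round(cfg.inducible_fraction * k)
    age_split: dict[str, dict[str, list[str]]] = {}
    inducible: dict[str, list[str]] = {}
    for sp, genus, _ in species_rows:
        pool = np.array(pools[sp])
        excl = rng.choice(pool, size=n_age, replace=False)
        young_only = sorted(excl[: n_age // 2])
        mature_only = sorted(excl[n_age // 2:])
        age_split[sp] = {"young_only": young_only, "mature_only": mature_only}
        inducible[sp] = sorted(rng.choice(pool, size=n_ind, replace=False))

    unused = [c for c in all_ids if c not in used]
    if len(unused) < cfg.n_contaminants:
        raise ConfigurationError(
            f"n_contaminants: only {len(unused)} library compounds left unused")
    contaminants = sorted(rng.choice(np.array(unused), size=cfg.n_contaminants,
                                     replace=False)) if cfg.n_contaminants else []

    base = {cid: 10.0 ** rng.uniform(0.0, 3.0) for cid in all_ids}

    # assemble samples
    plan: list[dict] = []
    for genus in design.genera:
        focal = design.focal_species[genus]
        counts = design.focal_cells(focal)
        for (age, treat), n in zip(_CELLS, counts):
            for r in range(n):
                plan.append(dict(species=focal, genus=genus, leaf_age=age,
                                 treatment=treat, sample_type="leaf", rep=r + 1))
        for j in range(design.genera[genus]):
            plan.append(dict(species=f"{genus}_sp{j + 1:02d}", genus=genus,
                             leaf_age="young", treatment="control",
                             sample_type="leaf", rep=1))
    for b in range(design.include_blanks):
        plan.append(dict(species="none", genus="none", leaf_age="none",
                         treatment="none", sample_type="blank", rep=b + 1))

    rows: dict[str, dict[str, float]] = {}
    meta_rows: list[dict] = []
    for entry in plan:
        if entry["sample_type"] == "blank":
            sid = f"blank_{entry['rep']}"
            expressed = list(contaminants)
            fold = {}
        else:
            sp = entry["species"]
            sid = (f"{sp}_{entry['leaf_age'][0]}"
                   f"{'J' if entry['treatment'] == 'JA' else 'C'}{entry['rep']}")
            drop = (age_split[sp]["mature_only"] if entry["leaf_age"] == "young"
                    else age_split[sp]["young_only"])
            expressed = [c for c in pools[sp] if c not in set(drop)]
            fold = ({c: cfg.induction_fold for c in inducible[sp]}
                    if entry["treatment"] == "JA" else {})
        noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=len(expressed)))
        rows[sid] = {c: base[c] * fold.get(c, 1.0) * n
                     for c, n in zip(expressed, noise)}
        meta_rows.append(dict(sample_id=sid, species=entry["species"],
                              genus=entry["genus"], leaf_age=entry["leaf_age"],
                              treatment=entry["treatment"],
                              sample_type=entry["sample_type"]))

    columns = sorted({c for r in rows.values() for c in r})
    table = pd.DataFrame(0.0, index=list(rows), columns=columns)
    for sid, vals in rows.items():
        table.loc[sid, list(vals)] = list(vals.values())
    table.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows)

    truth = {
        "seed": int(cfg.seed),
        "compound_class": {c.id: c.class_id for c in library.compounds
                           if c.id in set(columns)},
        "species_pools": pools,
        "age_splits": age_split,
        "inducible": inducible,
        "contaminants": list(contaminants),
        "cell_counts": {sp: list(design.focal_cells(sp))
                        for sp in design.focal_species.values()},
        "n_leaf_samples": int((meta["sample_type"] == "leaf").sum()),
    }
    return table, meta, truth


def generate_study_fixture(design: StudyDesign, cfg: EffectConfig,
                           out_dir: str | Path, n_replicates: int = 3,
                           mz_jitter: float = 0.005, intensity_cv: float = 0.2
                           ) -> dict[str, Path]:
    """Write the full file bundle: MGF spectra, feature CSV, metadata CSV,
    compound table (precursor m/z per feature) and the truth JSON.

    Deterministic: re-running with the same design, config and seed yields
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, meta, truth = simulate_feature_table(design, cfg)
    observed = set(table.columns)
    lib_subset = [c for c in generate_compound_library(cfg).compounds
                  if c.id in observed]
    spectra = simulate_spectra(lib_subset, n_replicates_per_compound=n_replicates,
                               mz_jitter=mz_jitter, intensity_cv=intensity_cv,
                               seed=np.random.SeedSequence([int(cfg.seed), 2]))
    paths = {
        "mgf": out / "spectra.mgf",
        "features": out / "features.csv",
        "metadata": out / "metadata.csv",
        "compounds": out / "compounds.csv",
        "truth": out / "truth.json",
    }
    write_mgf(spectra, paths["mgf"])
    table.to_csv(paths["features"], float_format="%.6f")
    meta.to_csv(paths["metadata"], index=False)
    pd.DataFrame({"compound_id": [c.id for c in lib_subset],
                  "precursor_mz": [f"{c.precursor_mz:.5f}" for c in lib_subset]}
                 ).to_csv(paths["compounds"], index=False)
    with paths["truth"].open("w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
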