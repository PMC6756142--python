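"""End-to-end pipeline: fixture -> network -> similarity -> tests -> report.

Stages communicate through files under ``out_dir`` so they can run in one
call (:func:`run_pipeline`) or as separate CLI invocations.  Every stage is
deterministic under a fixed seed; per-test permutation seeds are drawn from
one root generator in a fixed order and recorded in the output tables.

The factor tests reproduce the study's report structure:

* treatment effect per focal species, stratified by leaf age;
* leaf-age effect per focal species, controlling for treatment;
* species effect per genus, contrasting within-focal-species pairs (all
  ages and treatments pooled) against focal x congener young-control pairs;
* weighted-Z combined rows across species, and one-sided Wilcoxon contrasts
  of total ion intensity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FoliarchemError
from .inference import (classical_mds, constrained_permutation_test,
                        weighted_z_combine, wilcoxon_one_sided)
from .network import (build_network, cluster_spectra, component_summary,
                      subtract_blanks)
from .similarity import pairwise_matrix, total_ion_intensity
from .spectra import read_mgf
from .synthetic import (EffectConfig, default_effect_config, default_study_design,
                        generate_study_fixture)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("fixture", "network", "similarity", "test", "report")


@dataclass
class PipelineConfig:
    """Structured pipeline configuration (loadable from YAML).

    With ``use_fixture`` the input bundle is generated under
    ``out_dir/fixture``; otherwise ``mgf``, ``features``, ``metadata`` (and
    optionally ``compounds``) must point at existing files.
    """

    out_dir: Path = Path("foliarchem_out")
    use_fixture: bool = True
    effect: dict = field(default_factory=dict)      # EffectConfig overrides
    mgf: Path | None = None
    features: Path | None = None
    metadata: Path | None = None
    score_threshold: float = 0.6
    cluster_threshold: float = 0.95
    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    intensity_power: float = 0.5
    min_blank_intensity: float = 0.0
    metrics: tuple[str, ...] = ("CSCS", "BC")
    n_perm: int = 999
    seed: int = 0
    p_mode: str = "corrected"
    mds_dimensions: int = 2
    make_figures: bool = True

    def __post_init__(self) -> None:
        for name in ("score_threshold", "cluster_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        if self.p_mode not in ("paper", "corrected"):
            raise ConfigurationError(f"p_mode must be 'paper' or 'corrected', got {self.p_mode}")
        for m in self.metrics:
            if m not in ("CSCS", "BC"):
                raise ConfigurationError(f"unknown metric {m!r}")
        self.out_dir = Path(self.out_dir)
        for name in ("mgf", "features", "metadata"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        d["metrics"] = list(self.metrics)
        return d

    def effect_config(self) -> EffectConfig:
        return default_effect_config(**{**{"seed": self.seed}, **self.effect})

    def input_paths(self) -> dict[str, Path]:
        if self.use_fixture:
            fx = self.out_dir / "fixture"
            return {"mgf": fx / "spectra.mgf", "features": fx / "features.csv",
                    "metadata": fx / "metadata.csv"}
        missing = [n for n in ("mgf", "features", "metadata") if getattr(self, n) is None]
        if missing:
            raise ConfigurationError(f"input paths not configured: {missing}")
        return {"mgf": self.mgf, "features": self.features, "metadata": self.metadata}

    def check_inputs_exist(self) -> None:
        for name, p in self.input_paths().items():
            if not Path(p).exists():
                raise ConfigurationError(f"input file for {name!r} not found: {p}")


def _mark_failed(out_dir: Path, stage: str, exc: Exception) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "failed").write_text(f"stage: {stage}\nerror: {exc}\n")


def _feature_of(spectrum_id: str) -> str:
    """MGF TITLE contract: ``<feature_id>.<replicate>``."""
    return spectrum_id.rsplit(".", 1)[0]


def stage_fixture(cfg: PipelineConfig) -> dict[str, Path]:
    design = default_study_design()
    return generate_study_fixture(design, cfg.effect_config(), cfg.out_dir / "fixture")


def stage_network(cfg: PipelineConfig) -> dict:
    """Cluster spectra into consensus compounds and build the network.

    Cluster-level edges are projected onto feature ids (the majority feature
    id among each cluster's member spectra) keeping the maximum score per
    feature pair; the feature-level edge list is what the similarity stage
    consumes as the chemical structural similarity (css) support.
    """
    cfg.check_inputs_exist()
    spectra = read_mgf(cfg.input_paths()["mgf"])
    compounds, assignment = cluster_spectra(
        spectra, cluster_threshold=cfg.cluster_threshold,
        precursor_tol=cfg.precursor_tol, fragment_tol=cfg.fragment_tol,
        intensity_power=cfg.intensity_power)
    net = build_network(compounds, fragment_tol=cfg.fragment_tol,
                        score_threshold=cfg.score_threshold,
                        intensity_power=cfg.intensity_power)
    sizes, singletons = component_summary(net)

    members: dict[str, list[str]] = {c.id: c.member_ids for c in compounds}
    feat_of = {}
    for cid, mids in members.items():
        feats = pd.Series([_feature_of(m) for m in mids])
        feat_of[cid] = feats.mode().iloc[0]
    feature_edges: dict[tuple[str, str], float] = {}
    for i, j, s in net.edges:
        fi, fj = feat_of[i], feat_of[j]
        if fi == fj:
            continue
        key = (min(fi, fj), max(fi, fj))
        feature_edges[key] = max(feature_edges.get(key, 0.0), s)

    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    net.write_edgelist(out / "network_clusters.tsv")
    net.write_graphml(out / "network.graphml")
    with (out / "network_features.tsv").open("w") as fh:
        fh.write("node_i\tnode_j\tscore\n")
        for (fi, fj), s in sorted(feature_edges.items()):
            fh.write(f"{fi}\t{fj}\t{s:.6f}\n")
    pd.DataFrame({"spectrum_id": list(assignment),
                  "cluster_id": [assignment[s] for s in assignment],
                  "feature_id": [feat_of[assignment[s]] for s in assignment]}
                 ).to_csv(out / "cluster_assignment.csv", index=False)
    summary = {"n_spectra": len(spectra), "n_compounds": len(compounds),
               "n_edges_clusters": len(net.edges),
               "n_edges_features": len(feature_edges),
               "component_sizes": sizes, "n_singletons": singletons}
    with (out / "network_summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _load_feature_edges(path: Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(r.node_i, r.node_j, float(r.score)) for r in df.itertuples()]


def _css_for(columns: Sequence[str], edges: list[tuple[str, str, float]]) -> pd.DataFrame:
    pos = {c: k for k, c in enumerate(columns)}
    m = np.eye(len(columns))
    for i, j, s in edges:
        if i in pos and j in pos:
            m[pos[i], pos[j]] = m[pos[j], pos[i]] = s
    return pd.DataFrame(m, index=list(columns), columns=list(columns))


def _load_tables(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    paths = cfg.input_paths()
    table = pd.read_csv(paths["features"], index_col=0)
    meta = pd.read_csv(paths["metadata"])
    return table, meta


def stage_similarity(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    cfg.check_inputs_exist()
    table, meta = _load_tables(cfg)
    table = subtract_blanks(table, meta, cfg.min_blank_intensity)
    edges = _load_feature_edges(cfg.out_dir / "network_features.tsv")
    out = cfg.out_dir
    results: dict[str, pd.DataFrame] = {}
    for metric in cfg.metrics:
        css = _css_for(table.columns, edges) if metric == "CSCS" else None
        sim = pairwise_matrix(table, metric, css=css)
        sim.to_csv(out / f"similarity_{metric.lower()}.csv", float_format="%.10f")
        results[metric] = sim
    tii = total_ion_intensity(table)
    tii.rename("total_ion_intensity").to_csv(out / "total_ion_intensity.csv",
                                             float_format="%.6f")
    results["TII"] = tii.to_frame()
    return results


def _combine_rows(rows: list[dict], analysis: str, metric: str,
                  stratum: str | None) -> dict:
    """Weighted-Z combination across species rows (sqrt pair-count weights)."""
    ps = [r["p_corrected"] for r in rows]
    ws = [np.sqrt(r["n_within"] + r["n_between"]) for r in rows]
    ps = list(np.clip(ps, 1e-6, 1 - 1e-6))
    comb = weighted_z_combine(ps, ws)
    return dict(analysis=analysis, group="combined", stratum=stratum, metric=metric,
                within=np.nan, between=np.nan, delta=np.nan,
                p_paper=np.nan, p_corrected=np.nan, p=comb.p_combined,
                n_within=sum(r["n_within"] for r in rows),
                n_between=sum(r["n_between"] for r in rows),
                n_perm=np.nan, seed=np.nan, row_type="combined")


def _delta_row(res, analysis, group, stratum, metric) -> dict:
    return dict(analysis=analysis, group=group, stratum=stratum, metric=metric,
                within=res.within_mean, between=res.between_mean, delta=res.delta,
                p_paper=res.p_paper, p_corrected=res.p_corrected, p=res.p_value,
                n_within=res.n_within_pairs, n_between=res.n_between_pairs,
                n_perm=res.n_perm, seed=res.seed, row_type="group")


def stage_test(cfg: PipelineConfig, sims: dict[str, pd.DataFrame] | None = None
               ) -> pd.DataFrame:
    if sims is None:
        sims = {m: pd.read_csv(cfg.out_dir / f"similarity_{m.lower()}.csv", index_col=0)
                for m in cfg.metrics}
        sims["TII"] = pd.read_csv(cfg.out_dir / "total_ion_intensity.csv", index_col=0)
    _, meta = _load_tables(cfg)
    meta = meta[meta["sample_type"] == "leaf"].set_index("sample_id")
    design = default_study_design() if cfg.use_fixture else None
    focal = _infer_focal(meta, design)
    seeder = np.random.default_rng(cfg.seed)

    def next_seed() -> int:
        return int(seeder.integers(2 ** 31))

    rows: list[dict] = []
    tii = sims["TII"].iloc[:, 0]

    # treatment effect, stratified by leaf age
    for age in ("young", "mature"):
        for metric in cfg.metrics:
            species_rows = []
            for genus, sp in focal.items():
                ids = meta.index[(meta["species"] == sp) & (meta["leaf_age"] == age)]
                res = constrained_permutation_test(
                    sims[metric], meta, "treatment", subset=list(ids),
                    n_perm=cfg.n_perm, seed=next_seed(), p_mode=cfg.p_mode)
                row = _delta_row(res, "treatment", sp, age, metric)
                rows.append(row)
                species_rows.append(row)
            rows.append(_combine_rows(species_rows, "treatment", metric, age))
        # total ion intensity: JA vs control, one-sided greater
        tii_rows = []
        for genus, sp in focal.items():
            sub = meta[(meta["species"] == sp) & (meta["leaf_age"] == age)]
            x = tii[sub.index[sub["treatment"] == "JA"]]
            y = tii[sub.index[sub["treatment"] == "control"]]
            p = wilcoxon_one_sided(x, y)
            row = dict(analysis="treatment", group=sp, stratum=age, metric="TII",
                       within=float(x.mean()), between=float(y.mean()),
                       delta=float(x.mean() - y.mean()), p_paper=np.nan,
                       p_corrected=float(np.clip(p, 1e-6, 1 - 1e-6)), p=p,
                       n_within=len(x), n_between=len(y), n_perm=np.nan,
                       seed=np.nan, row_type="group")
            rows.append(row)
            tii_rows.append(row)
        rows.append(_combine_rows(tii_rows, "treatment", "TII", age))

    # leaf-age effect, controlling for treatment
    for metric in cfg.metrics:
        species_rows = []
        for genus, sp in focal.items():
            ids = meta.index[meta["species"] == sp]
            res = constrained_permutation_test(
                sims[metric], meta, "leaf_age", control="treatment",
                subset=list(ids), n_perm=cfg.n_perm, seed=next_seed(),
                p_mode=cfg.p_mode)
            row = _delta_row(res, "leaf_age", sp, None, metric)
            rows.append(row)
            species_rows.append(row)
        rows.append(_combine_rows(species_rows, "leaf_age", metric, None))
    tii_rows = []
    for genus, sp in focal.items():
        sub = meta[(meta["species"] == sp) & (meta["treatment"] == "control")]
        x = tii[sub.index[sub["leaf_age"] == "young"]]
        y = tii[sub.index[sub["leaf_age"] == "mature"]]
        p = wilcoxon_one_sided(x, y)
        row = dict(analysis="leaf_age", group=sp, stratum="control", metric="TII",
                   within=float(x.mean()), between=float(y.mean()),
                   delta=float(x.mean() - y.mean()), p_paper=np.nan,
                   p_corrected=float(np.clip(p, 1e-6, 1 - 1e-6)), p=p,
                   n_within=len(x), n_between=len(y), n_perm=np.nan,
                   seed=np.nan, row_type="group")
        rows.append(row)
        tii_rows.append(row)
    rows.append(_combine_rows(tii_rows, "leaf_age", "TII", "control"))

    # species effect per genus: within focal pairs vs focal x congener pairs
    for metric in cfg.metrics:
        for genus, sp in focal.items():
            in_genus = meta["genus"] == genus
            congener = in_genus & (meta["species"] != sp) & \
                (meta["leaf_age"] == "young") & (meta["treatment"] == "control")
            ids = list(meta.index[(meta["species"] == sp) | congener])
            res = constrained_permutation_test(
                sims[metric], meta, "species", subset=ids, focal_level=sp,
                n_perm=cfg.n_perm, seed=next_seed(), p_mode=cfg.p_mode)
            rows.append(_delta_row(res, "species", genus, None, metric))

    df = pd.DataFrame(rows)
    df.to_csv(cfg.out_dir / "results.csv", index=False, float_format="%.6f")
    return df


def _infer_focal(meta: pd.DataFrame, design=None) -> dict[str, str]:
    """Focal species per genus: the species with replicated sampling."""
    if design is not None:
        return dict(design.focal_species)
    focal = {}
    for genus, sub in meta.groupby("genus"):
        counts = sub["species"].value_counts()
        focal[genus] = counts.idxmax()
    return focal


def stage_report(cfg: PipelineConfig, sims=None, results=None) -> dict:
    if sims is None:
        sims = {m: pd.read_csv(cfg.out_dir / f"similarity_{m.lower()}.csv", index_col=0)
                for m in cfg.metrics}
    _, meta = _load_tables(cfg)
    meta = meta[meta["sample_type"] == "leaf"].set_index("sample_id")
    design = default_study_design() if cfg.use_fixture else None
    focal = set(_infer_focal(meta, design).values())
    focal_ids = [s for s in meta.index if meta.loc[s, "species"] in focal]

    metric = "CSCS" if "CSCS" in cfg.metrics else cfg.metrics[0]
    sim = sims[metric].loc[focal_ids, focal_ids]
    coords = classical_mds(sim, k=cfg.mds_dimensions)
    coords = coords.join(meta[["species", "leaf_age", "treatment"]])
    coords.to_csv(cfg.out_dir / "mds_coordinates.csv", float_format="%.8f")

    if cfg.make_figures:
        _mds_figure(coords, cfg.out_dir / "mds_cscs.svg")
        _similarity_boxplot(sims, meta, cfg.out_dir / "similarity_boxplot.svg")

    cfg_dict = cfg.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    provenance = {"config": cfg_dict,
                  "config_sha256": hashlib.sha256(blob).hexdigest(),
                  "seed": cfg.seed}
    with (cfg.out_dir / "provenance.json").open("w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return provenance


def _mds_figure(coords: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    species = sorted(coords["species"].unique())
    cmap = plt.get_cmap("tab10")
    for k, sp in enumerate(species):
        for age, marker in (("young", "^"), ("mature", "o")):
            for treat, alpha in (("JA", 1.0), ("control", 0.4)):
                sel = coords[(coords["species"] == sp) & (coords["leaf_age"] == age)
                             & (coords["treatment"] == treat)]
                if len(sel):
                    ax.scatter(sel["MDS1"], sel["MDS2"], color=cmap(k), marker=marker,
                               alpha=alpha, label=f"{sp} {age} {treat}", s=30)
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    ax.legend(fontsize=5, loc="best")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _similarity_boxplot(sims, meta, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    metrics = [m for m in sims if m != "TII"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4),
                             squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sim = sims[metric]
        ids = [s for s in sim.index if s in meta.index]
        sp = meta.loc[ids, "species"].to_numpy()
        m = sim.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), 1)
        same = sp[iu[0]] == sp[iu[1]]
        ax.boxplot([m[iu][same], m[iu][~same]], tick_labels=["within sp.", "between sp."])
        ax.set_ylabel(f"{metric} similarity")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in order; on failure, write a ``failed``
    marker naming the stage and re-raise."""
    bundle: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "fixture" and not cfg.use_fixture:
            continue
        try:
            if stage == "fixture":
                bundle["fixture"] = stage_fixture(cfg)
            elif stage == "network":
                bundle["network"] = stage_network(cfg)
            elif stage == "similarity":
                bundle["similarity"] = stage_similarity(cfg)
            elif stage == "test":
                bundle["results"] = stage_test(cfg, bundle.get("similarity"))
            elif stage == "report":
                bundle["report"] = stage_report(cfg, bundle.get("similarity"))
        except (FoliarchemError, OSError, ValueError, KeyError) as exc:
            _mark_failed(cfg.out_dir, stage, exc)
            raise FoliarchemError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
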