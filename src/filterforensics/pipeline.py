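"""One-command orchestration of the full analysis on a study's inputs.

For each assay the pipeline runs, in order: singleton removal → negative-
control subtraction → rarefaction; then, on the rarefied table, qPCR
quantification with bootstrap CV comparison, alpha-diversity/core summaries,
beta-diversity statistics (distance matrix → PCoA, PERMANOVA, dispersion
test, core-vs-global Mantel per sample type), and indicator-panel source
attribution.  The result is a single nested report dict serialized as
deterministic JSON: same inputs + same seed ⇒ byte-identical output.

Per-stage random streams are derived from the single pipeline seed with
fixed offsets, so adding permutations to one stage never shifts another.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import attribution as attr_mod
from . import beta as beta_mod
from . import diversity as div_mod
from . import permstats
from . import preprocess as prep
from . import qpcr as qpcr_mod
from .io_model import (
    DistanceMatrix,
    FeatureTable,
    Metadata,
    PhyloTree,
    TaxonomyMap,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_distance_matrix,
    write_feature_table,
)
from .preprocess import ControlProfile
from .qpcr import QpcrRecord

SCHEMA_VERSION = "1.0"

# fixed per-stage seed offsets (stage streams must not interleave)
_STAGE_OFFSETS = {
    "rarefy": 1,
    "permanova": 2,
    "dispersion": 3,
    "mantel": 4,
    "bootstrap": 5,
}


def _stage_seed(seed: int, stage: str, salt: int = 0) -> int:
    ss = np.random.SeedSequence([int(seed), _STAGE_OFFSETS[stage], salt])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


@dataclass
class AssayInputs:
    """All pipeline inputs for one assay, already parsed."""

    name: str  # "bacteria" | "fungi"
    table: FeatureTable
    metadata: Metadata
    taxonomy: TaxonomyMap
    tree: Optional[PhyloTree]
    controls: list[ControlProfile]
    qpcr_records: list[QpcrRecord]
    standard_points: list[tuple[float, float]]
    organism: str  # operon-copy calibrant key
    metric: str  # beta-diversity metric for this assay


@dataclass
class PipelineConfig:
    seed: int
    rarefy_depth: object = "auto"  # "auto" | int
    n_permutations: int = 999
    n_boot: int = 10000
    unifrac_variant: str = "weighted_unifrac_normalized"
    renormalize_core: bool = True
    output_dir: Optional[Path] = None
    panels: list = field(default_factory=attr_mod.builtin_panels)


def core_vs_global_mantel(
    table: FeatureTable,
    sample_ids,
    group: str,
    metric: str,
    tree: Optional[PhyloTree],
    n_perm: int,
    seed: Optional[int],
    renormalize: bool = True,
) -> permstats.MantelResult:
    """Mantel correlation between the group-core-restricted and global matrices.

    The core OTUs of ``group`` are computed on its samples; the distance
    matrix over ALL samples restricted to those OTUs (renormalized to
    proportions over the core by default) is correlated with the all-OTU
    matrix.
    """
    core = div_mod.core_microbiome(table, sample_ids, group)
    if not core.core_otu_ids:
        raise ValueError(f"group {group!r} has an empty core")
    global_dm = beta_mod.distance_matrix(table, metric, tree)
    core_table = table.select_otus(core.core_otu_ids)
    if renormalize:
        core_table = prep.relative_abundance(core_table)
    core_dm = beta_mod.distance_matrix(core_table, metric, tree)
    return permstats.mantel(core_dm, global_dm, n_perm=n_perm, seed=seed)


def _cv_block(
    quantities: dict[str, float], metadata: Metadata, cfg: PipelineConfig, salt: int
) -> dict:
    """Per-method CV ± bootstrap CI and pairwise CV-difference CIs."""
    methods = [m for m in metadata.methods_present() if m != "control"]
    by_method = {
        m: np.array([quantities[s] for s in metadata.samples_with_method(m) if s in quantities])
        for m in methods
    }
    out: dict = {"per_method": {}, "differences": {}}
    for m in methods:
        v = by_method[m]
        if v.size < 3:
            continue
        res = permstats.bootstrap_cv(
            v, n_boot=cfg.n_boot, seed=_stage_seed(cfg.seed, "bootstrap", salt)
        )
        out["per_method"][m] = {
            "cv": round(res.cv, 6),
            "ci_low": round(res.ci_low, 6),
            "ci_high": round(res.ci_high, 6),
        }
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            if by_method[a].size < 3 or by_method[b].size < 3:
                continue
            d = permstats.bootstrap_cv_difference(
                by_method[a],
                by_method[b],
                n_boot=cfg.n_boot,
                seed=_stage_seed(cfg.seed, "bootstrap", salt + 1),
            )
            out["differences"][f"{a}_minus_{b}"] = {
                "cv_difference": round(d.cv, 6),
                "ci_low_95": round(d.ci_low, 6),
                "ci_high_95": round(d.ci_high, 6),
                "excludes_zero_95": d.excludes_zero_95,
                "excludes_zero_90": d.excludes_zero_90,
            }
    return out


def run_assay(inputs: AssayInputs, cfg: PipelineConfig) -> dict:
    """Run every analysis stage for one assay; returns the report sub-dict."""
    report: dict = {}

    # --- preprocessing: singletons -> control subtraction -> rarefaction ---
    rarefied, depth = prep.preprocess_pipeline(
        inputs.table,
        inputs.controls,
        inputs.metadata,
        depth=cfg.rarefy_depth,
        seed=_stage_seed(cfg.seed, "rarefy"),
    )
    report["preprocess"] = {
        "rarefy_depth": depth,
        "n_samples": rarefied.n_samples,
        "n_otus_input": inputs.table.n_otus,
        "n_otus_after_singletons": rarefied.n_otus,
        "n_otus_observed": int(np.count_nonzero(rarefied.otu_sums() > 0)),
    }

    methods = [m for m in inputs.metadata.methods_present() if m != "control"]
    meta = inputs.metadata

    # --- qPCR quantification + CV bootstrap --------------------------------
    if inputs.qpcr_records:
        curve = qpcr_mod.fit_standard_curve(inputs.standard_points)
        quantities: dict[str, float] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rec in inputs.qpcr_records:
                row = meta.frame.loc[rec.sample_id]
                mass = row.get("dust_mass_mg")
                mass = None if mass is None or pd.isna(mass) else float(mass)
                q = qpcr_mod.quantify(
                    rec, curve, inputs.organism, float(row["sampled_area_cm2"]), mass
                )
                quantities[rec.sample_id] = q.per_area
        report["qpcr"] = {
            "curve": {
                "slope": round(curve.slope, 6),
                "intercept": round(curve.intercept, 6),
                "efficiency": round(curve.efficiency, 6),
                "r_squared": round(curve.r_squared, 6),
            },
            "per_area_median": {
                m: round(float(np.median([quantities[s] for s in meta.samples_with_method(m)])), 4)
                for m in methods
            },
            "cv": _cv_block(
                quantities, meta, cfg, salt=zlib.crc32(inputs.name.encode()) % 1000
            ),
        }

    # --- alpha diversity / membership --------------------------------------
    div_block: dict = {}
    for m in methods:
        sids = [s for s in meta.samples_with_method(m) if s in rarefied.sample_ids]
        if not sids:
            continue
        core = div_mod.core_microbiome(rarefied, sids, m)
        div_block[m] = {
            "richness": div_mod.richness(rarefied, sids),
            "k50": div_mod.min_otus_for_fraction(rarefied, sids, 0.5),
            "core_n_otus": len(core.core_otu_ids),
            "core_pct_otus": round(core.pct_of_group_otus, 4),
            "core_pct_reads": round(core.pct_of_group_reads, 4),
        }
    div_block["singleton_occupancy_pct"] = round(
        div_mod.singleton_fraction(rarefied), 4
    )
    report["diversity"] = div_block

    # --- beta diversity + permutation statistics ---------------------------
    tree = inputs.tree
    dm = beta_mod.distance_matrix(rarefied, inputs.metric, tree)
    groups = meta.groups_for(dm.ids, "method")
    ordn = beta_mod.pcoa(dm)
    pmv = permstats.permanova(
        dm, groups, n_perm=cfg.n_permutations, seed=_stage_seed(cfg.seed, "permanova")
    )
    disp = permstats.dispersion_test(
        dm, groups, n_perm=cfg.n_permutations, seed=_stage_seed(cfg.seed, "dispersion")
    )
    mantels = {}
    for salt, m in enumerate(methods):
        sids = [s for s in meta.samples_with_method(m) if s in rarefied.sample_ids]
        try:
            mr = core_vs_global_mantel(
                rarefied, sids, m, inputs.metric, tree,
                n_perm=cfg.n_permutations,
                seed=_stage_seed(cfg.seed, "mantel", salt),
                renormalize=cfg.renormalize_core,
            )
            mantels[m] = {"r": round(mr.r, 6), "p_value": round(mr.p_value, 6)}
        except ValueError as exc:
            mantels[m] = {"error": str(exc)}
    report["beta"] = {
        "metric": inputs.metric,
        "pcoa_pct_explained": [
            round(100 * float(p), 2) for p in ordn.proportion_explained[:2]
        ],
        "permanova": {
            "pseudo_F": round(pmv.pseudo_F, 6),
            "r_squared": round(pmv.r_squared, 6),
            "p_value": round(pmv.p_value, 6),
            "n_permutations": pmv.n_permutations,
        },
        "dispersion": {
            "global_F": round(disp.global_F, 6),
            "global_p": round(disp.global_p, 6),
            "parametric_p": round(disp.parametric_p, 6),
            "mean_distance_to_centroid": {
                g: round(float(v.mean()), 6) for g, v in disp.group_distances.items()
            },
            "pairwise_tukey": {
                f"{a}_vs_{b}": round(p, 6) for a, b, p in disp.pairwise
            },
        },
        "core_vs_global_mantel": mantels,
    }

    # --- source attribution -------------------------------------------------
    rel = prep.relative_abundance(rarefied)
    attr_block = {}
    for panel in cfg.panels:
        vals = attr_mod.panel_abundance(rel, inputs.taxonomy, panel)
        summary = attr_mod.group_summary(vals, rel.sample_ids, meta)
        attr_block[panel.name] = {
            g: {
                "mean_pct": round(100 * mean, 4),
                "se_pct": None if se is None else round(100 * se, 4),
            }
            for g, (mean, se) in summary.items()
        }
    report["attribution"] = attr_block

    if cfg.output_dir is not None:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(rarefied, outdir / f"{inputs.name}_rarefied.tsv")
        write_distance_matrix(dm, outdir / f"{inputs.name}_distances.tsv")
    return report


def run_pipeline(assays: list[AssayInputs], cfg: PipelineConfig) -> dict:
    """Run all assays and assemble the versioned report."""
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": int(cfg.seed),
        "n_permutations": int(cfg.n_permutations),
        "n_boot": int(cfg.n_boot),
        "assays": {},
    }
    for inputs in assays:
        try:
            report["assays"][inputs.name] = run_assay(inputs, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for assay {inputs.name!r} "
                f"({inputs.table.n_samples} samples x {inputs.table.n_otus} OTUs): {exc}"
            ) from exc
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# File-based entry (used by the CLI)
# ---------------------------------------------------------------------------

def read_controls_table(path, metadata: Metadata) -> list[ControlProfile]:
    """Controls stored as a classic table whose sample columns are method names."""
    table = read_feature_table(path)
    profiles = []
    for method in table.sample_ids:
        i = table.sample_index(method)
        counts = {
            otu: float(c)
            for otu, c in zip(table.otu_ids, table.counts[i])
            if c > 0
        }
        profiles.append(ControlProfile(sample_type=method, counts=counts))
    return profiles


def read_qpcr_records(path) -> list[QpcrRecord]:
    """One well per row: sample_id, assay, cq, dilution, template_uL, elution_uL."""
    frame = pd.read_csv(path, sep="\t")
    records = []
    for (sid, assay), grp in frame.groupby(["sample_id", "assay"], sort=False):
        records.append(
            QpcrRecord(
                sample_id=str(sid),
                assay=str(assay),
                cq_triplicate=list(grp["cq"].astype(float)),
                dilution_factor=float(grp["dilution_factor"].iloc[0]),
                template_volume_uL=float(grp["template_volume_uL"].iloc[0]),
                elution_volume_uL=float(grp["elution_volume_uL"].iloc[0]),
            )
        )
    return records


def read_standard_points(path) -> list[tuple[float, float]]:
    frame = pd.read_csv(path, sep="\t")
    return [
        (float(r["log10_copies"]), float(r["mean_cq"])) for _, r in frame.iterrows()
    ]


def load_assay_inputs(
    name: str,
    table_path,
    metadata_path,
    taxonomy_path=None,
    tree_path=None,
    controls_path=None,
    qpcr_path=None,
    standards_path=None,
    metric: Optional[str] = None,
) -> AssayInputs:
    metadata = read_metadata(metadata_path)
    table = read_feature_table(table_path)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else TaxonomyMap()
    tree = read_tree(tree_path) if tree_path else None
    controls = read_controls_table(controls_path, metadata) if controls_path else []
    records = read_qpcr_records(qpcr_path) if qpcr_path else []
    points = read_standard_points(standards_path) if standards_path else []
    if metric is None:
        metric = "weighted_unifrac_normalized" if tree is not None else "morisita_horn"
    organism = "bacteria_ecoli_o157" if name == "bacteria" else "fungi_aniger"
    return AssayInputs(
        name=name,
        table=table,
        metadata=metadata,
        taxonomy=taxonomy,
        tree=tree,
        controls=controls,
        qpcr_records=records,
        standard_points=points,
        organism=organism,
        metric=metric,
    )
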