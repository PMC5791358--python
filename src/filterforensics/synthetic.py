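"""Synthetic study generator.

Emulates the study design the pipeline was built for: one HVAC filter
sampled by three dust-recovery methods (cut, swab, vacuum) with seven
replicates each, every replicate a composite of five randomly placed
2.5 × 2.5 cm filter squares.  The generative model is:

* a long-tailed "true" community: lognormal(0, sigma) relative abundances
  over ``n_otus``, normalized;
* per-method multiplicative recovery bias (by default the cut method
  suppresses a designated "hydrophobic" OTU subset, mimicking the loss of
  hydrophobic-walled fungi to the buffer-elution protocol);
* replicate noise: each of the 5 patches is a Dirichlet draw around the
  biased community with per-method concentration (lower = noisier), the
  replicate composition is the patch average, and reads are a multinomial
  draw at a Poisson depth — the standard Dirichlet-multinomial picture of
  microbiome counts;
* negative-control contamination: small Poisson counts on a random OTU
  subset per method;
* qPCR biomass: per-replicate genome density per cm² drawn lognormal with a
  per-method generative CV, pushed through a synthetic standard curve to Cq
  triplicates (so the qpcr module can invert it).

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io_model import (
    FeatureTable,
    Lineage,
    Metadata,
    PhyloTree,
    TaxonomyMap,
    parse_lineage,
    read_tree,
)
from .preprocess import ControlProfile
from .qpcr import OPERON_COPIES, QpcrRecord, fit_standard_curve

METHODS = ("cut", "swab", "vacuum")
SAMPLED_AREA_CM2 = 5 * 2.5 * 2.5  # five 2.5x2.5 cm squares per composite


@dataclass
class Scenario:
    """Generative study conditions for one assay."""

    assay: str = "bacteria"  # "bacteria" | "fungi"
    n_otus: int = 2000
    n_replicates: int = 7
    depth_mean: dict = field(
        default_factory=lambda: {"cut": 20000, "swab": 20000, "vacuum": 20000}
    )
    lognormal_sigma: float = 2.0
    # per-method Dirichlet concentration; lower = more replicate variability
    dispersion: dict = field(
        default_factory=lambda: {"cut": 20.0, "swab": 500.0, "vacuum": 500.0}
    )
    # fraction of OTUs marked hydrophobic and the cut-method recovery factor
    hydrophobic_fraction: float = 0.10
    cut_hydrophobic_bias: float = 0.2
    n_patches: int = 5
    contamination_rate: float = 5e-5
    # per-method generative CV of the qPCR genome density
    qpcr_cv: dict = field(
        default_factory=lambda: {"cut": 1.24, "swab": 0.31, "vacuum": 0.35}
    )
    # per-method median genome copies per cm^2
    qpcr_density: dict = field(
        default_factory=lambda: {"cut": 324.0, "swab": 623.0, "vacuum": 15380.0}
    )
    qpcr_noise_sd: float = 0.05  # well-to-well Cq noise, cycles
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per method")
        if any(v <= 0 for v in self.dispersion.values()):
            raise ValueError("dispersion must be > 0")
        if self.n_otus < 2 or self.n_patches < 1:
            raise ValueError("n_otus >= 2 and n_patches >= 1 required")


def fungi_scenario(**overrides) -> Scenario:
    """Fungal-assay defaults: smaller richness/depth, heavier cut variability."""
    base = Scenario(
        assay="fungi",
        n_otus=500,
        depth_mean={"cut": 2000, "swab": 2000, "vacuum": 2000},
        qpcr_cv={"cut": 1.86, "swab": 0.32, "vacuum": 0.42},
        qpcr_density={"cut": 1.0, "swab": 9.0, "vacuum": 79.0},
    )
    return replace(base, **overrides)


def bacteria_scenario(**overrides) -> Scenario:
    return replace(Scenario(), **overrides)


# ---------------------------------------------------------------------------
# Community + replicates
# ---------------------------------------------------------------------------

def simulate_base_community(scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    """Lognormal(0, sigma) relative abundances, normalized to sum 1."""
    raw = rng.lognormal(mean=0.0, sigma=scenario.lognormal_sigma, size=scenario.n_otus)
    return raw / raw.sum()


def method_bias_vectors(scenario: Scenario, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-method per-OTU recovery factors; cut suppresses the hydrophobic subset."""
    bias = {m: np.ones(scenario.n_otus) for m in METHODS}
    n_hydro = int(round(scenario.hydrophobic_fraction * scenario.n_otus))
    if n_hydro > 0 and scenario.cut_hydrophobic_bias != 1.0:
        hydro = rng.choice(scenario.n_otus, size=n_hydro, replace=False)
        bias["cut"] = bias["cut"].copy()
        bias["cut"][hydro] = scenario.cut_hydrophobic_bias
    return bias


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # gamma-based draw; tiny alphas can underflow to an all-zero vector,
    # in which case the most concentrated component takes the mass
    g = rng.gamma(np.maximum(alpha, 1e-12))
    s = g.sum()
    if s <= 0:
        out = np.zeros_like(g)
        out[np.argmax(alpha)] = 1.0
        return out
    return g / s


def simulate_replicates(
    scenario: Scenario,
    base: np.ndarray,
    rng: np.random.Generator,
    bias: Optional[dict[str, np.ndarray]] = None,
    methods=METHODS,
) -> tuple[FeatureTable, Metadata]:
    """Draw the full methods × replicates count table plus its metadata."""
    if not math.isclose(base.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("base community must sum to 1")
    if bias is None:
        bias = method_bias_vectors(scenario, rng)
    otu_ids = [f"OTU_{j:05d}" for j in range(scenario.n_otus)]
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows = []
    assay_label = "bacteria_16S" if scenario.assay == "bacteria" else "fungi_ITS"
    for method in methods:
        target = base * bias.get(method, 1.0)
        target = target / target.sum()
        alpha = scenario.dispersion[method] * target
        for r in range(scenario.n_replicates):
            patches = np.stack(
                [_dirichlet(rng, alpha) for _ in range(scenario.n_patches)]
            )
            comp = patches.mean(axis=0)
            depth = max(1, int(rng.poisson(scenario.depth_mean[method])))
            counts = rng.multinomial(depth, comp / comp.sum())
            sid = f"{method}_{r + 1}"
            sample_ids.append(sid)
            rows.append(counts.astype(float))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "method": method,
                    "household": "houseA",
                    "assay": assay_label,
                    "sampled_area_cm2": SAMPLED_AREA_CM2,
                    "dust_mass_mg": (
                        float(rng.lognormal(np.log(47.0), 0.2)) if method == "vacuum" else np.nan
                    ),
                }
            )
    table = FeatureTable(sample_ids, otu_ids, np.array(rows))
    meta = Metadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta


# ---------------------------------------------------------------------------
# Tree + taxonomy
# ---------------------------------------------------------------------------

def simulate_tree(otu_ids, seed) -> PhyloTree:
    """Random bifurcating rooted tree by sequential random joins, exp(1) lengths."""
    if len(otu_ids) < 2:
        raise ValueError("need >= 2 OTUs for a tree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subtrees = [f"{name}:{rng.exponential(1.0):.6f}" for name in otu_ids]
    while len(subtrees) > 1:
        i, j = rng.choice(len(subtrees), size=2, replace=False)
        a, b = subtrees[i], subtrees[j]
        merged = f"({a},{b}):{rng.exponential(1.0):.6f}"
        keep = [s for t, s in enumerate(subtrees) if t not in (i, j)]
        keep.append(merged)
        subtrees = keep
    # strip the root's own branch length
    newick = subtrees[0].rsplit(":", 1)[0] + ";"
    return read_tree(newick=newick)


_BACT_LINEAGES = [
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__Propionibacteriaceae; g__Propionibacterium",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Staphylococcaceae; g__Staphylococcus",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__Corynebacteriaceae; g__Corynebacterium",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Streptococcaceae; g__Streptococcus",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__Micrococcaceae; g__Rothia",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__Micrococcaceae; g__Micrococcus",
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Tissierellaceae; g__Anaerococcus",
    "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Bacteroidaceae; g__Bacteroides",
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Faecalibacterium",
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Blautia",
    "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Oscillospira",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; f__Bradyrhizobiaceae; g__Bradyrhizobium",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rhizobiales; f__Rhizobiaceae; g__Rhizobium",
    "k__Bacteria; p__Acidobacteria; c__Solibacteres; o__Solibacterales; f__Solibacteraceae; g__",
    "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Pseudomonadales; f__Pseudomonadaceae; g__Pseudomonas",
    "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Sphingomonadales; f__Sphingomonadaceae; g__Sphingomonas",
    "k__Bacteria; p__Bacteroidetes; c__Cytophagia; o__Cytophagales; f__Cytophagaceae; g__Hymenobacter",
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae; g__Bacillus",
    "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__Geodermatophilaceae; g__Modestobacter",
    "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Burkholderiales; f__Comamonadaceae; g__",
]

_FUNG_LINEAGES = [
    "k__Fungi; p__Ascomycota; c__Dothideomycetes; o__Pleosporales; f__Pleosporaceae; g__Alternaria",
    "k__Fungi; p__Ascomycota; c__Eurotiomycetes; o__Eurotiales; f__Trichocomaceae; g__Aspergillus",
    "k__Fungi; p__Ascomycota; c__Dothideomycetes; o__Capnodiales; f__Davidiellaceae; g__Cladosporium",
    "k__Fungi; p__Ascomycota; c__Dothideomycetes; o__Capnodiales; f__Davidiellaceae; g__Davidiella",
    "k__Fungi; p__Ascomycota; c__Saccharomycetes; o__Saccharomycetales; f__Saccharomycetaceae; g__Candida",
    "k__Fungi; p__Basidiomycota; c__Tremellomycetes; o__Tremellales; f__Tremellaceae; g__Cryptococcus",
    "k__Fungi; p__Basidiomycota; c__Exobasidiomycetes; o__Malasseziales; f__Malasseziaceae; g__Malassezia",
    "k__Fungi; p__Basidiomycota; c__Microbotryomycetes; o__Sporidiobolales; f__Sporidiobolaceae; g__Rhodotorula",
    "k__Fungi; p__Ascomycota; c__Saccharomycetes; o__Saccharomycetales; f__Saccharomycetaceae; g__Saccharomyces",
    "k__Fungi; p__Basidiomycota; c__Agaricomycetes; o__Polyporales; f__Polyporaceae; g__Trametes",
    "k__Fungi; p__Ascomycota; c__Sordariomycetes; o__Hypocreales; f__Nectriaceae; g__Fusarium",
    "k__Fungi; p__Basidiomycota; c__Agaricomycetes; o__Agaricales; f__Psathyrellaceae; g__Coprinellus",
    "k__Fungi; p__Ascomycota; c__Dothideomycetes; o__Dothideales; f__Dothioraceae; g__Aureobasidium",
    "k__Fungi; p__Ascomycota; c__Leotiomycetes; o__Helotiales; f__Sclerotiniaceae; g__Botrytis",
    "k__Fungi; p__Basidiomycota; c__Ustilaginomycetes; o__Ustilaginales; f__Ustilaginaceae; g__Ustilago",
]


def simulate_taxonomy(scenario: Scenario, rng: np.random.Generator, otu_ids) -> TaxonomyMap:
    """Assign each OTU a lineage from a plausible pool for the assay."""
    pool = _BACT_LINEAGES if scenario.assay == "bacteria" else _FUNG_LINEAGES
    lineages = [parse_lineage(s) for s in pool]
    tax = TaxonomyMap()
    picks = rng.integers(0, len(lineages), size=len(otu_ids))
    for otu, p in zip(otu_ids, picks):
        src = lineages[p]
        tax.assignments[otu] = Lineage(list(src.levels))
    return tax


# ---------------------------------------------------------------------------
# Controls + qPCR
# ---------------------------------------------------------------------------

def simulate_controls(
    scenario: Scenario, rng: np.random.Generator, otu_ids
) -> list[ControlProfile]:
    """One negative-control profile per method: Poisson contamination counts."""
    profiles = []
    n_subset = max(1, int(round(0.01 * scenario.n_otus)))
    for method in METHODS:
        counts: dict[str, float] = {}
        if scenario.contamination_rate > 0:
            subset = rng.choice(len(otu_ids), size=n_subset, replace=False)
            lam = scenario.contamination_rate * scenario.depth_mean[method]
            draws = rng.poisson(lam, size=n_subset)
            for j, c in zip(subset, draws):
                if c > 0:
                    counts[otu_ids[j]] = float(c)
        profiles.append(ControlProfile(sample_type=method, counts=counts))
    return profiles


def synthetic_standard_points(assay: str) -> list[tuple[float, float]]:
    """Perfect-efficiency dilution series (slope −log2(10), 7 decades)."""
    slope = -math.log2(10)  # -3.3219...: one cycle per doubling
    intercept = 38.0 if assay == "bacteria" else 36.0
    return [(float(lg), intercept + slope * lg) for lg in range(1, 8)]


def simulate_qpcr(
    scenario: Scenario,
    metadata: Metadata,
    rng: np.random.Generator,
) -> tuple[list[QpcrRecord], list[tuple[float, float]]]:
    """Per-replicate qPCR Cq triplicates consistent with the synthetic curve.

    The genome density per cm² is lognormal around the scenario's per-method
    median with the per-method generative CV; the forward chain (density →
    extract genomes → rRNA copies per diluted well → Cq) is the exact
    inverse of the qpcr module's quantification chain.
    """
    points = synthetic_standard_points(scenario.assay)
    curve = fit_standard_curve(points)
    organism = "bacteria_ecoli_o157" if scenario.assay == "bacteria" else "fungi_aniger"
    operons = OPERON_COPIES[organism]
    assay_label = "bacteria_16S" if scenario.assay == "bacteria" else "fungi_18S"
    dilution, template_uL, elution_uL = 100.0, 2.0, 50.0
    records = []
    truth: dict[str, float] = {}
    for sid in metadata.frame.index:
        method = metadata.method_of(sid)
        cv_gen = scenario.qpcr_cv[method]
        sigma = math.sqrt(math.log(1.0 + cv_gen**2))
        density = rng.lognormal(math.log(scenario.qpcr_density[method]), sigma)
        truth[sid] = density
        genomes_extract = density * SAMPLED_AREA_CM2
        genomes_reaction = genomes_extract * (template_uL / elution_uL)
        copies_well = genomes_reaction * operons / dilution
        cq_center = curve.intercept + curve.slope * math.log10(max(copies_well, 1e-12))
        cqs = cq_center + rng.normal(0.0, scenario.qpcr_noise_sd, size=3)
        cqs = np.clip(cqs, 1e-3, 44.999)
        records.append(
            QpcrRecord(
                sample_id=sid,
                assay=assay_label,
                cq_triplicate=list(cqs),
                dilution_factor=dilution,
                template_volume_uL=template_uL,
                elution_volume_uL=elution_uL,
            )
        )
    return records, points, truth


# ---------------------------------------------------------------------------
# Whole studies
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    scenario: Scenario
    table: FeatureTable
    metadata: Metadata
    tree: PhyloTree
    taxonomy: TaxonomyMap
    controls: list[ControlProfile]
    qpcr_records: list[QpcrRecord]
    standard_points: list[tuple[float, float]]
    base_community: np.ndarray
    qpcr_truth: dict[str, float] = field(default_factory=dict)


def simulate_study(scenario: Scenario, seed: Optional[int] = None) -> StudyData:
    """Generate all pipeline inputs for one assay under the scenario."""
    if seed is None:
        seed = scenario.seed if scenario.seed is not None else 0
    rng = np.random.default_rng(seed)
    base = simulate_base_community(scenario, rng)
    bias = method_bias_vectors(scenario, rng)
    table, metadata = simulate_replicates(scenario, base, rng, bias)
    tree = simulate_tree(table.otu_ids, rng)
    taxonomy = simulate_taxonomy(scenario, rng, table.otu_ids)
    controls = simulate_controls(scenario, rng, table.otu_ids)
    records, points, truth = simulate_qpcr(scenario, metadata, rng)
    return StudyData(
        scenario=scenario,
        table=table,
        metadata=metadata,
        tree=tree,
        taxonomy=taxonomy,
        controls=controls,
        qpcr_records=records,
        standard_points=points,
        base_community=base,
        qpcr_truth=truth,
    )


def simulate_multihome(
    n_households: int = 5,
    methods=("swab", "vacuum"),
    n_replicates: int = 2,
    n_otus: int = 400,
    depth: int = 5000,
    sigma: float = 2.0,
    concentration: float = 200.0,
    method_bias_strength: float = 0.8,
    seed: Optional[int] = None,
) -> tuple[FeatureTable, Metadata]:
    """Households × methods design: distinct base community per household,
    a small shared method bias — the regime where communities cluster by
    household rather than by sampling method."""
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{j:05d}" for j in range(n_otus)]
    biased = rng.choice(n_otus, size=max(1, n_otus // 10), replace=False)
    sample_ids, rows, meta_rows = [], [], []
    for h in range(n_households):
        raw = rng.lognormal(0.0, sigma, size=n_otus)
        base = raw / raw.sum()
        for method in methods:
            target = base.copy()
            if method == methods[0]:
                target[biased] *= method_bias_strength
            target /= target.sum()
            alpha = concentration * target
            for r in range(n_replicates):
                comp = _dirichlet(rng, alpha)
                counts = rng.multinomial(depth, comp)
                sid = f"house{h}_{method}_{r + 1}"
                sample_ids.append(sid)
                rows.append(counts.astype(float))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "method": method,
                        "household": f"house{h}",
                        "assay": "bacteria_16S",
                        "sampled_area_cm2": SAMPLED_AREA_CM2,
                        "dust_mass_mg": np.nan,
                    }
                )
    table = FeatureTable(sample_ids, otu_ids, np.array(rows))
    meta = Metadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta
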