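"""Source attribution via indicator-taxon panels.

Curated name lists (human-indicator bacterial families, skin and stool
genera, soil/marine/insect taxa, allergenic and human-skin fungi) are
matched against OTU lineages at their stated ranks, and the matched
relative abundance is summed per sample, then summarized per sample type as
mean ± SE.  Matching is exact (case-insensitive) at the entry's rank after
stripping ``f__``-style prefixes — panels are curated name lists, so fuzzy
matching would only invite false credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_model import FeatureTable, Metadata, TaxonomyMap


@dataclass
class IndicatorPanel:
    name: str
    entries: list[tuple[str, str]]  # (taxon_name, rank)
    source_tag: str
    partial: bool = False  # True when the source list was truncated ("among others")

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"panel {self.name!r} has no entries")
        names = [t.lower() for t, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"panel {self.name!r} has duplicate taxon names")


_HUMAN_FAMILIES = [
    "Corynebacteriaceae", "Staphylococcaceae", "Streptococcaceae",
    "Lactobacillaceae", "Propionibacteriaceae", "Peptostreptococcaceae",
    "Bifidobacteriaceae", "Micrococcaceae", "Dietziaceae", "Aerococcaceae",
    "Tissierellaceae",
]
_SKIN_GENERA = [
    "Propionibacterium", "Staphylococcus", "Corynebacterium", "Streptococcus",
    "Rothia", "Micrococcus", "Anaerococcus", "Brevibacterium",
]
_STOOL_GENERA = [
    "Bacteroides", "Faecalibacterium", "Lachnospira", "Oscillospira",
    "Roseburia", "Coprococcus", "Ruminococcus", "Parabacteroides",
    "Phascolarctobacterium", "Sutterella", "Blautia",
]
_FUNGAL_SKIN_GENERA = [
    "Candida", "Cryptococcus", "Malassezia", "Rhodotorula", "Saccharomyces",
]


def builtin_panels() -> list[IndicatorPanel]:
    """The built-in indicator panels (soil/marine/insect/allergen are partial lists)."""
    return [
        IndicatorPanel(
            "human_families",
            [(f, "family") for f in _HUMAN_FAMILIES],
            source_tag="human",
        ),
        IndicatorPanel(
            "skin_genera", [(g, "genus") for g in _SKIN_GENERA], source_tag="skin"
        ),
        IndicatorPanel(
            "stool_genera", [(g, "genus") for g in _STOOL_GENERA], source_tag="stool"
        ),
        IndicatorPanel(
            "soil",
            [
                ("Solibacteraceae", "family"),
                ("Chloracidobacteria", "class"),
                ("Bradyrhizobium", "genus"),
                ("Rhizobium", "genus"),
            ],
            source_tag="soil",
            partial=True,
        ),
        IndicatorPanel(
            "marine",
            [
                ("Pelagibacteraceae", "family"),
                ("Synechococcus", "genus"),
                ("Marinobacter", "genus"),
                ("Polaribacter", "genus"),
            ],
            source_tag="marine",
            partial=True,
        ),
        IndicatorPanel(
            "insect",
            [
                ("Wolbachia", "genus"),
                ("Buchnera", "genus"),
                ("Rickettsiella", "genus"),
                ("Blattabacterium", "genus"),
                ("Baumannia", "genus"),
            ],
            source_tag="insect",
            partial=True,
        ),
        IndicatorPanel(
            "fungal_allergen",
            [
                ("Alternaria", "genus"),
                ("Aspergillus", "genus"),
                # family-level entry: covers Cladosporium/Davidiella jointly
                ("Davidiellaceae", "family"),
            ],
            source_tag="fungal_allergen",
            partial=True,
        ),
        IndicatorPanel(
            "fungal_skin",
            [(g, "genus") for g in _FUNGAL_SKIN_GENERA],
            source_tag="fungal_skin",
        ),
    ]


def panel_abundance(
    table: FeatureTable, taxonomy: TaxonomyMap, panel: IndicatorPanel
) -> np.ndarray:
    """Per-sample summed proportion of OTUs matching the panel.

    ``table`` must hold relative abundances (rows sum to 1).  An OTU matches
    if its lineage name at an entry's rank equals the entry name
    (case-insensitive); OTUs without taxonomy simply never match.
    """
    sums = table.sample_sums()
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("panel_abundance expects a relative-abundance table")
    wanted: dict[str, set[str]] = {}
    for taxon, rank in panel.entries:
        wanted.setdefault(rank, set()).add(taxon.lower())
    mask = np.zeros(table.n_otus, dtype=bool)
    for j, otu in enumerate(table.otu_ids):
        lineage = taxonomy.get(otu)
        if lineage is None:
            continue
        for rank, names in wanted.items():
            name = lineage.name_at(rank)
            if name is not None and name.lower() in names:
                mask[j] = True
                break
    return table.counts[:, mask].sum(axis=1)


def group_summary(
    per_sample_values: Sequence[float],
    sample_ids: Sequence[str],
    metadata: Metadata,
    column: str = "method",
) -> dict[str, tuple[float, Optional[float]]]:
    """Mean and SE (sd/√n) of a per-sample statistic within each group.

    Groups with a single sample report the mean with SE ``None``.
    """
    vals = np.asarray(per_sample_values, dtype=float)
    groups = metadata.groups_for(sample_ids, column)
    out: dict[str, tuple[float, Optional[float]]] = {}
    for g in dict.fromkeys(groups):
        v = vals[groups == g]
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else None
        out[str(g)] = (float(v.mean()), se)
    return out
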