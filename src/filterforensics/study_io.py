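"""Write a synthetic study to disk in the pipeline's input formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io_model import (
    FeatureTable,
    write_feature_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from .synthetic import StudyData


def write_study(study: StudyData, outdir) -> dict[str, Path]:
    """Write table/metadata/tree/taxonomy/controls/qPCR files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = study.scenario.assay
    paths = {
        "table": outdir / f"{prefix}_table.tsv",
        "metadata": outdir / f"{prefix}_metadata.tsv",
        "tree": outdir / f"{prefix}_tree.nwk",
        "taxonomy": outdir / f"{prefix}_taxonomy.tsv",
        "controls": outdir / f"{prefix}_controls.tsv",
        "qpcr": outdir / f"{prefix}_qpcr.tsv",
        "standards": outdir / f"{prefix}_standards.tsv",
    }
    write_feature_table(study.table, paths["table"])
    write_metadata(study.metadata, paths["metadata"])
    write_tree(study.tree, paths["tree"])
    write_taxonomy(study.taxonomy, paths["taxonomy"])

    # controls: classic table with one column per method profile
    methods = [p.sample_type for p in study.controls]
    otu_order = list(study.table.otu_ids)
    pos = {o: j for j, o in enumerate(otu_order)}
    mat = np.zeros((len(methods), len(otu_order)))
    for i, profile in enumerate(study.controls):
        for otu, c in profile.counts.items():
            mat[i, pos[otu]] = c
    nonzero = mat.sum(axis=0) > 0
    ctrl_table = FeatureTable(
        methods,
        [o for o, k in zip(otu_order, nonzero) if k],
        mat[:, nonzero],
    )
    write_feature_table(ctrl_table, paths["controls"])

    with open(paths["qpcr"], "w") as fh:
        fh.write(
            "sample_id\tassay\twell\tcq\tdilution_factor\ttemplate_volume_uL\telution_volume_uL\n"
        )
        for rec in study.qpcr_records:
            for w, cq in enumerate(rec.cq_triplicate, start=1):
                fh.write(
                    f"{rec.sample_id}\t{rec.assay}\t{w}\t{cq:.6f}\t"
                    f"{rec.dilution_factor}\t{rec.template_volume_uL}\t{rec.elution_volume_uL}\n"
                )

    with open(paths["standards"], "w") as fh:
        fh.write("log10_copies\tmean_cq\n")
        for lg, cq in study.standard_points:
            fh.write(f"{lg}\t{cq:.6f}\n")
    return paths
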