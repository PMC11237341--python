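"""Pipeline orchestration: chain the stages and emit the report bundle.

A run takes a set of annotated genomes (GenBank files or simulated), and
writes per-feature characteristics, per-genome and per-region composition,
RSCU, per-gene Ka/Ks, the concatenated-PCG supermatrix with partition
definitions, an NJ + bootstrap tree, and a JSON summary with validation
issues, spacer accounting, seed and per-stage timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import FeatureType, MitoGenome, spacer_report, validate
from .codons import extract_cds, format_stop, rscu
from .composition import base_composition, region_table
from .composition import round_row
from .io_formats import write_newick, write_supermatrix
from .kaks import gene_kaks
from .phylo import bootstrap, build_gene_alignments, concatenate_pcgs

ALL_STAGES = ("validate", "characterize", "rscu", "kaks", "supermatrix", "tree")


@dataclass
class RunConfig:
    outdir: Path
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    bootstrap_replicates: int = 100
    outgroup: str | None = None
    lenient: bool = False
    distance_model: str = "JC69"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


class StageError(RuntimeError):
    pass


def feature_rows(g: MitoGenome) -> pd.DataFrame:
    rep = spacer_report(g)
    spacers = {pair[0]: pair[2] for pair in rep.per_pair}
    rows = []
    for f in g.features:
        length = (len(g) - f.start + 1) + f.end if f.wraps else f.end - f.start + 1
        rows.append(
            {
                "genome": g.taxon,
                "name": f.name,
                "type": f.ftype.value,
                "start": f.start,
                "end": f.end,
                "length": length,
                "strand": f.strand.value,
                "start_codon": f.start_codon or "",
                "stop_codon": format_stop(f.stop_codon),
                "anticodon": f.anticodon or "",
                "spacer_to_next": spacers.get(f.name, 0),
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig, genomes: list[MitoGenome]) -> dict:
    """Execute the requested stages; returns the summary dict.

    On stage failure, partial outputs are kept and MANIFEST.json records the
    completion state before the error is re-raised as :class:`StageError`.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "genomes": [g.taxon for g in genomes],
        "timings_s": {},
    }

    def finish(stage: str, t0: float, state: str = "ok") -> None:
        manifest[stage] = state
        summary["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "validate":
                mode = "lenient" if config.lenient else "strict"
                issues = {g.taxon: validate(g, mode) for g in genomes}
                summary["validation"] = issues
                if any(issues.values()) and not config.lenient:
                    finish(stage, t0, "failed")
                    raise StageError(f"strict validation failed: {issues}")
            elif stage == "characterize":
                pd.concat([feature_rows(g) for g in genomes]).to_csv(
                    out / "table1.tsv", sep="\t", index=False
                )
                comp = pd.DataFrame(
                    [
                        {"species": g.taxon, "accession": g.accession,
                         **round_row(base_composition(g.sequence, g.taxon))}
                        for g in genomes
                    ]
                )
                comp.to_csv(out / "table2.tsv", sep="\t", index=False)
                regions = []
                for g in genomes:
                    for row in region_table(g):
                        regions.append({"genome": g.taxon, **round_row(row)})
                pd.DataFrame(regions).to_csv(out / "table3.tsv", sep="\t", index=False)
                summary["spacer_reports"] = {
                    g.taxon: {
                        "overlap_bp_total": (r := spacer_report(g)).overlap_bp_total,
                        "overlap_pairs": r.overlap_pairs,
                        "ign_bp_total": r.ign_bp_total,
                        "ign_locations": r.ign_locations,
                    }
                    for g in genomes
                }
            elif stage == "rscu":
                rows = []
                for g in genomes:
                    table = rscu([extract_cds(g, f.name) for f in g.pcgs()])
                    for codon, aa, count, val in table.to_rows():
                        rows.append(
                            {"genome": g.taxon, "codon": codon.replace("T", "U"),
                             "amino_acid": aa, "count": count, "rscu": round(val, 3)}
                        )
                pd.DataFrame(rows).to_csv(out / "rscu.tsv", sep="\t", index=False)
            elif stage == "kaks":
                if len(genomes) < 2:
                    finish(stage, t0, "skipped: <2 genomes")
                    continue
                blocks = build_gene_alignments(genomes)
                rows = []
                for gene, block in blocks.items():
                    est = gene_kaks(dict(zip(block.taxa, block.rows)), gene)
                    rows.append(
                        {"gene": gene, "Ka": round(est.Ka_mean, 4),
                         "Ks": round(est.Ks_mean, 4),
                         "KaKs": round(est.ratio, 4) if est.ratio is not None else "",
                         "n_pairs": est.n_pairs}
                    )
                pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
            elif stage == "supermatrix":
                if len(genomes) < 2:
                    finish(stage, t0, "skipped: <2 genomes")
                    continue
                sm = concatenate_pcgs({}, genomes)
                write_supermatrix(sm, out / "supermatrix.phy", "relaxed_phylip")
                write_supermatrix(sm, out / "supermatrix.nex", "nexus")
            elif stage == "tree":
                if len(genomes) < 4:
                    finish(stage, t0, "skipped: <4 genomes")
                    continue
                sm = concatenate_pcgs({}, genomes)
                tree = bootstrap(sm, config.bootstrap_replicates, config.seed,
                                 config.distance_model)
                (out / "tree.nwk").write_text(write_newick(tree) + "\n")
            finish(stage, t0)
    finally:
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
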