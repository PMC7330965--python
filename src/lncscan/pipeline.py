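"""End-to-end orchestration: identify -> AS events -> expression -> targets.

All thresholds live in one :class:`RunConfig`; every default equals the
screening criterion the analysis applies (candidate length/exon rules,
100-aa ORF cutoff, FPKM 0.1 presence, 100-kb cis window, 0.6/0.9
correlation thresholds, q<0.01 and |log2FC|>1 for differential abundance).
Outputs are plain TSV/GTF plus a short markdown report; reruns with an
identical config are byte-identical.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import annotation_io as aio
from . import as_events as ase
from . import expression as expr
from . import lnc_identify as ident
from . import target_predict as tp

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("lncscan")


@dataclass
class RunConfig:
    assembly: str = ""
    reference: str = ""
    genome: str = ""
    counts: str = ""
    min_length: int = 200
    min_exons: int = 2
    orf_max_aa: int = 100
    presence_fpkm: float = 0.1
    cis_window: int = 100_000
    cis_r: float = 0.6
    trans_r: float = 0.9
    alpha: float = 0.05
    dal_q: float = 0.01
    dal_log2fc: float = 1.0
    ndg_cut: float = -0.1
    require_complementarity: bool = True
    count_mode: str = "locus"  # AS events: locus | pairwise
    dal_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.min_length <= 0 or self.min_exons <= 0 or self.orf_max_aa <= 0:
            raise ValueError("thresholds must be positive")
        if self.cis_window <= 0:
            raise ValueError("cis window must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data["dal_pairs"] = [tuple(p) for p in data.get("dal_pairs", [])]
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s failed", name)
                raise
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_all(config: RunConfig, outdir: str) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict of the in-memory stage results (identification result,
    event lists, summaries, expression matrix, DAL and target tables).
    """
    os.makedirs(outdir, exist_ok=True)
    for label in ("assembly", "reference", "genome", "counts"):
        path = getattr(config, label)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"{label} file not found: {path!r}")

    assembly = aio.read_gtf(config.assembly)
    reference = aio.read_gtf(config.reference)
    genome = aio.read_fasta(config.genome)
    counts = aio.read_counts(config.counts)
    log.info(
        "inputs: %d assembly genes, %d reference genes, %d chromosomes, "
        "%d x %d count table",
        len(assembly), len(reference), len(genome),
        counts.counts.shape[0], counts.counts.shape[1],
    )

    result = _stage("identify")(ident.run_identification)(
        assembly, reference, genome, counts,
        min_length=config.min_length, min_exons=config.min_exons,
        orf_max_aa=config.orf_max_aa,
    )
    log.info(
        "identified %d lncRNAs (%s)", len(result.records),
        ", ".join(f"{k}={v}" for k, v in result.per_class.items()),
    )

    lnc_txs = [r.transcript for r in result.records]
    aio.write_gtf(lnc_txs, os.path.join(outdir, "lncRNA.gtf"))
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "class": r.positional_class.value,
                "spliced_length": r.transcript.spliced_length,
                "n_exons": r.transcript.n_exons,
                "longest_orf_nt": r.longest_orf_nt,
            }
            for r in result.records
        ]
    ).to_csv(os.path.join(outdir, "classes.tsv"), sep="\t", index=False)
    result.per_chromosome.to_csv(os.path.join(outdir, "per_chromosome.tsv"), sep="\t")

    # --- AS events over the identified lncRNA loci ----------------------
    events = []
    n_spliced = 0
    for locus in _stage("asevents")(ase.group_loci)(lnc_txs):
        n_spliced += len(locus)
        if len(locus) >= 2:
            events.extend(ase.locus_events(locus, count_mode=config.count_mode))
    summary, frac = ase.summarize_events(events, n_spliced)
    pd.DataFrame(
        [
            {
                "event_type": e.event_type,
                "isoform_a": e.isoform_a,
                "isoform_b": e.isoform_b,
                "region_start": e.region[0],
                "region_end": e.region[1],
                "strand": e.strand,
            }
            for e in events
        ]
    ).to_csv(os.path.join(outdir, "events.tsv"), sep="\t", index=False)
    summary.to_frame().to_csv(os.path.join(outdir, "table1.tsv"), sep="\t")
    log.info("AS: %d events, spliced fraction %.2f%%", summary.total, frac)

    # --- expression ------------------------------------------------------
    lengths = pd.Series(
        {
            t.transcript_id: t.spliced_length
            for g in assembly
            for t in g.transcripts
            if t.transcript_id in counts.counts.index
        }
    )
    table = aio.CountTable(
        counts=counts.counts.loc[lengths.index], library_totals=counts.library_totals
    )
    em = _stage("express")(expr.fpkm)(table, lengths)
    em.presence_threshold = config.presence_fpkm
    em.fpkm.round(4).to_csv(os.path.join(outdir, "fpkm.tsv"), sep="\t")

    lnc_ids = [r.transcript_id for r in result.records]
    seed_libs = [l for l in em.library_ids if "seed" in l.lower()]
    venn = expr.venn_partition(
        em, lnc_ids, seed_libraries=seed_libs or None
    )
    venn_rows = [
        {"subset": "+".join(sorted(s)) if s else "(absent)", "n": n}
        for s, n in sorted(
            venn.subset_counts.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
        )
    ]
    pd.DataFrame(venn_rows).to_csv(
        os.path.join(outdir, "venn.tsv"), sep="\t", index=False
    )

    pairs = config.dal_pairs or (
        [tuple(em.library_ids[:2])] if len(em.library_ids) >= 2 else []
    )
    dal_records = []
    for pair in pairs:
        dal_records.extend(
            _stage("dal")(expr.dal_call)(
                table, pair, q_max=config.dal_q, min_log2fc=config.dal_log2fc
            )
        )
    dal_lnc = [d for d in dal_records if d.transcript_id in set(lnc_ids)]
    pd.DataFrame([d.__dict__ for d in dal_lnc]).to_csv(
        os.path.join(outdir, "dal.tsv"), sep="\t", index=False
    )
    log.info("DALs: %d lncRNAs across %d pairs", len(dal_lnc), len(pairs))

    # --- targets ----------------------------------------------------------
    targets = _stage("targets")(tp.predict_targets)(
        result.records, reference, em, genome,
        window=config.cis_window, cis_r=config.cis_r, trans_r=config.trans_r,
        alpha=config.alpha, ndg_cut=config.ndg_cut,
        require_complementarity=config.require_complementarity,
    )
    pd.DataFrame([t.__dict__ for t in targets]).to_csv(
        os.path.join(outdir, "targets.tsv"), sep="\t", index=False
    )
    log.info("targets: %d pairs", len(targets))

    _write_report(outdir, result, summary, frac, venn, dal_lnc, targets)
    return {
        "identification": result,
        "events": events,
        "summary": summary,
        "spliced_fraction": frac,
        "expression": em,
        "venn": venn,
        "dal": dal_lnc,
        "targets": targets,
    }


def _write_report(outdir, result, summary, frac, venn, dal, targets) -> None:
    lines = ["# lncscan run report", ""]
    lines.append("## Identification")
    total = len(result.records)
    lines.append(f"- lncRNAs identified: {total}")
    for k, v in result.per_class.items():
        pct = 100.0 * v / total if total else 0.0
        lines.append(f"  - {k}: {v} ({pct:.2f}%)")
    for bucket in ("filter_failed", "coding", "sense_overlap", "genic_other"):
        lines.append(f"- dropped ({bucket}): {len(result.buckets[bucket])}")
    r, p = result.chrom_correlation
    lines.append(
        f"- per-chromosome lncRNA vs transcribed-gene correlation: "
        f"r={r:.3f} (p={p:.3g})"
    )
    lines.append("")
    lines.append("## Alternative splicing")
    lines.append(f"- events: {summary.total}; spliced fraction {frac:.2f}%")
    for t in ("TSS", "TTS", "ES", "IR", "AE"):
        lines.append(
            f"  - {t}: {summary.counts[t]} ({summary.percentages[t]:.2f}%)"
        )
    lines.append("")
    lines.append("## Expression")
    lines.append(f"- present in all libraries: {venn.n_all_libraries}")
    lines.append(f"- library-specific: {venn.library_specific}")
    lines.append(f"- differentially abundant lncRNAs: {len(dal)}")
    lines.append("")
    lines.append("## Targets")
    n_cis = sum(1 for t in targets if t.mode == "cis")
    lines.append(f"- cis: {n_cis}, trans: {len(targets) - n_cis}")
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
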