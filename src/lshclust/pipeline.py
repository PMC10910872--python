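"""File-level pipeline: FASTA in, cluster TSV / representative FASTA out.

Thin orchestration over :class:`~lshclust.estimator.LSHClusterer`; all
outputs are deterministic for a fixed config (canonically sorted before
writing), so re-runs are byte-identical.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .alphabet import SequenceRecord, normalize_residues
from .align import ClusterCriteria
from .estimator import LSHClusterer
from .graph import Clustering, cascade_cluster
from .lsh import MaskFamily

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "write_clusters",
    "read_clusters",
    "write_report",
    "run_cluster",
]


@dataclass
class RunConfig:
    input: str | Path
    output_prefix: str | Path
    min_identity: float = 0.3
    min_coverage: float = 0.8
    k: int = 12
    d: int = 3
    n_tables: int = 24
    radius: int = 2
    alphabet: str = "murphy10"
    cascade: Sequence[float] = ()  # e.g. (0.9, 0.3); overrides min_identity
    mask_family_path: str | Path | None = None
    rounds: int = 3
    degree_cap: int = 10
    max_bucket: int | None = None
    skip_ambiguous: bool = False
    n_jobs: int = 1
    seed: int = 0


def read_fasta(path) -> list[SequenceRecord]:
    """Parse FASTA; ids are the first whitespace token; residues uppercased,
    '*' and gaps stripped, ambiguity codes collapsed to X; duplicate ids
    rejected."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_residues(str(rec.seq))))
    if not records and Path(path).stat().st_size > 0:
        raise ValueError(f"{path} contains no FASTA records")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def write_clusters(clustering: Clustering, path) -> None:
    """Two-column TSV, representative TAB member, sorted, one line per input
    sequence."""
    with open(path, "w") as fh:
        for member, rep in sorted(
            clustering.assignment.items(), key=lambda kv: (kv[1], kv[0])
        ):
            fh.write(f"{rep}\t{member}\n")


def read_clusters(path) -> Clustering:
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            rep, member = ln.split("\t")
            assignment[member] = rep
    return Clustering(assignment=assignment)


def write_report(report: dict, path) -> None:
    """Flat key=value text (nested dicts dotted)."""
    def _items(d, prefix=""):
        for k, v in d.items():
            if isinstance(v, dict):
                yield from _items(v, prefix + k + ".")
            else:
                yield prefix + k, v

    with open(path, "w") as fh:
        for k, v in _items(report):
            fh.write(f"{k}={v}\n")


def run_cluster(config: RunConfig, log=sys.stderr) -> tuple[Clustering, dict]:
    """End-to-end run: read, (cascade-)cluster, write outputs.

    Writes ``<prefix>.clusters.tsv``, ``<prefix>.reps.fasta``,
    ``<prefix>.masks.txt`` and ``<prefix>.report.txt``.  With a cascade
    (e.g. 0.9 then 0.3) the final outputs carry the composed deep
    assignment and per-stage TSVs are written alongside.
    """
    t0 = time.perf_counter()
    records = read_fasta(config.input)
    by_id = {r.id: r for r in records}
    mask_family = (
        MaskFamily.load(config.mask_family_path)
        if config.mask_family_path
        else None
    )

    def _make(min_identity: float) -> LSHClusterer:
        return LSHClusterer(
            min_identity=min_identity,
            min_coverage=config.min_coverage,
            k=config.k, d=config.d, n_tables=config.n_tables,
            radius=config.radius, alphabet=config.alphabet,
            mask_family=mask_family, rounds=config.rounds,
            degree_cap=config.degree_cap, max_bucket=config.max_bucket,
            skip_ambiguous=config.skip_ambiguous, n_jobs=config.n_jobs,
            seed=config.seed,
        )

    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"input": str(config.input), "seed": config.seed}}

    if config.cascade:
        stages = [
            ClusterCriteria(mi, config.min_coverage) for mi in config.cascade
        ]
        first_est = _make(config.cascade[0])

        def _cluster_fn(recs, crit):
            est = _make(crit.min_identity)
            est.mask_family = first_est._resolve_family()
            est.fit(list(recs.values()))
            return est.clustering_

        stage_outputs, composed = cascade_cluster(by_id, stages, _cluster_fn)
        for crit, st in zip(stages, stage_outputs):
            write_clusters(
                st, f"{prefix}.stage{int(round(crit.min_identity * 100))}.tsv"
            )
        clustering = Clustering(assignment=composed, criteria=stages[-1])
        family_used = first_est._resolve_family()
        report["stages"] = {
            f"id{int(round(c.min_identity * 100))}.n_clusters":
                len(st.representatives)
            for c, st in zip(stages, stage_outputs)
        }
    else:
        est = _make(config.min_identity).fit(records)
        clustering = est.clustering_
        family_used = est.mask_family_
        report.update(est.report_)

    write_clusters(clustering, f"{prefix}.clusters.tsv")
    reps = clustering.representatives
    write_fasta([by_id[r] for r in reps], f"{prefix}.reps.fasta")
    family_used.save(f"{prefix}.masks.txt", r=config.radius)
    report["n_clusters_final"] = len(reps)
    report["wall_s"] = round(time.perf_counter() - t0, 3)
    write_report(report, f"{prefix}.report.txt")
    if log is not None:
        print(
            f"[lshclust] {len(records)} sequences -> {len(reps)} clusters "
            f"in {report['wall_s']}s",
            file=log,
        )
    return clustering, report
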