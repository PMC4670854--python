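"""File dialects: FASTA, dot-bracket structure files, TSV tables.

All on-disk coordinates are 1-based inclusive (miRBase convention); all
in-memory coordinates are 0-based half-open.  The converters here are the
single crossing point between the two systems.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from sklearn.datasets import dump_svmlight_file

from .hairpin import HairpinAlignment, HairpinError, PreMiRNA
from .predict import DeviationReport, PredictionResult
from .synthetic import AnnotationRecord, SyntheticDataset

ANNOTATION_COLUMNS = ["premirna_id", "mature_id", "start", "end", "arm"]


def to_one_based(span: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    start, end = span
    return start + 1, end


def to_zero_based(span: tuple[int, int]) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    start, end = span
    return start - 1, end


def read_fasta(path: str | Path) -> list[PreMiRNA]:
    return [
        PreMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[PreMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_structures(path: str | Path, records: list[PreMiRNA]) -> list[PreMiRNA]:
    """Attach dot-bracket lines (one per record, same order) to records."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != len(records):
        raise HairpinError(
            f"{len(lines)} structure lines for {len(records)} FASTA records"
        )
    return [
        PreMiRNA(rec.id, rec.sequence, struct)
        for rec, struct in zip(records, lines)
    ]


def write_structures(records: list[PreMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.structure is None:
                raise HairpinError(f"{rec.id}: structure absent")
            fh.write(rec.structure + "\n")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"premirna_id": str, "mature_id": str})
    missing = set(ANNOTATION_COLUMNS) - {*df.columns, "arm"}
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        start, end = to_zero_based((int(row.start), int(row.end)))
        arm = getattr(row, "arm", "")
        arm = "" if pd.isna(arm) else arm
        out.append(
            AnnotationRecord(
                premirna_id=row.premirna_id,
                mature_id=row.mature_id,
                start=start,
                end=end,
                arm=str(arm),
            )
        )
    return out


def write_annotations(annotations: list[AnnotationRecord], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        start, end = to_one_based((ann.start, ann.end))
        rows.append(
            {
                "premirna_id": ann.premirna_id,
                "mature_id": ann.mature_id,
                "start": start,
                "end": end,
                "arm": ann.arm,
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def derive_arm(ann: AnnotationRecord, alignment: HairpinAlignment) -> str:
    """Infer which arm hosts an annotation from its coordinates."""
    loop_start, loop_end = alignment.loop_span
    if ann.end <= loop_start:
        return "5p"
    if ann.start >= loop_end:
        return "3p"
    raise ValueError(
        f"{ann.mature_id}: span overlaps the terminal loop, no arm assignable"
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset as FASTA + structures + annotation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "precursors.fa",
        "structures": outdir / "precursors.db",
        "annotations": outdir / "annotations.tsv",
    }
    write_fasta(dataset.records, paths["fasta"])
    write_structures(dataset.records, paths["structures"])
    write_annotations(dataset.annotations, paths["annotations"])
    return paths


def write_predictions(
    results: dict[str, PredictionResult], path: str | Path
) -> None:
    """One row per ranked candidate: id, arm, start (1-based), scenario, p."""
    rows = []
    for res in results.values():
        for arm in ("5p", "3p"):
            for rank, cand in enumerate(res.ranked[arm], start=1):
                rows.append(
                    {
                        "premirna_id": res.premirna_id,
                        "arm": arm,
                        "rank": rank,
                        "start": cand.mature_start + 1,
                        "scenario": cand.scenario,
                        "p_positive": cand.p_positive,
                    }
                )
    pd.DataFrame(
        rows,
        columns=["premirna_id", "arm", "rank", "start", "scenario", "p_positive"],
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"premirna_id": str})


def write_ds_table(report: DeviationReport, path: str | Path) -> None:
    """DS/AD summary in the conventional one-row layout (+-0 ... +-10, AD)."""
    row = {f"+-{k}": report.ds[k] for k in range(len(report.ds))}
    row["AD"] = report.ad
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def export_libsvm(X, y, path: str | Path) -> None:
    """Training matrix in libSVM sparse text format for cross-tool checks."""
    with open(path, "wb") as fh:
        dump_svmlight_file(X, y, fh, zero_based=False)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
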