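"""Annotation, probe and matrix I/O plus strand-aware promoter windows.

All interval logic in this package is 0-based, half-open ``[start, end)``,
matching BED. A promoter window spans ``upstream`` bp before to
``downstream`` bp after the transcription start site (TSS), read in the
direction of transcription; the default −2000/+500 window is the span
covered by the tiled promoter array this package emulates.
"""

from __future__ import annotations

import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss"]
PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "is_background"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check an annotation frame (gene_id, chrom, strand, tss) and return it.

    Raises ``ValueError`` on duplicate gene ids, negative TSS coordinates
    or strands outside {+, -}.
    """
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annotation["gene_id"].duplicated().any():
        dup = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id: {dup!r}")
    if (annotation["tss"] < 0).any():
        raise ValueError("negative tss coordinate")
    bad = ~annotation["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"unknown strand {annotation.loc[bad, 'strand'].iloc[0]!r}"
        )
    return annotation


def promoter_windows(
    annotation: pd.DataFrame, upstream: int = 2000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter windows, one per gene, clipped at 0.

    For a plus-strand gene the window is ``[tss - upstream, tss + downstream)``;
    for a minus-strand gene it is the mirror image
    ``[tss - downstream + 1, tss + upstream + 1)``, so that the window read
    in transcription direction covers the same −upstream..+downstream span.
    """
    validate_annotation(annotation)
    ann = annotation.reset_index(drop=True)
    plus = ann["strand"] == "+"
    start = pd.Series(0, index=ann.index, dtype="int64")
    end = pd.Series(0, index=ann.index, dtype="int64")
    start[plus] = ann.loc[plus, "tss"] - upstream
    end[plus] = ann.loc[plus, "tss"] + downstream
    start[~plus] = ann.loc[~plus, "tss"] - downstream + 1
    end[~plus] = ann.loc[~plus, "tss"] + upstream + 1
    start = start.clip(lower=0)
    return pd.DataFrame(
        {
            "gene_id": ann["gene_id"],
            "chrom": ann["chrom"],
            "start": start,
            "end": end,
            "strand": ann["strand"],
            "tss": ann["tss"],
        }
    )


# ---------------------------------------------------------------------------
# File I/O. Plain TSV with header for tables, BED for intervals.
# ---------------------------------------------------------------------------

def write_annotation(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation)
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    try:
        return validate_annotation(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into the annotation frame.

    Only rows of type ``gene`` are used; the TSS is the start for
    plus-strand and end−1 for minus-strand features (GFF3 is 1-based
    closed, so coordinates are shifted to 0-based).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype != "gene":
                continue
            gid = None
            for field in attrs.split(";"):
                key, _, val = field.partition("=")
                if key.strip() == "ID":
                    gid = val.strip()
            if gid is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID")
            s, e = int(start) - 1, int(end)
            tss = s if strand == "+" else e - 1
            rows.append((gid, chrom, strand, tss))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    try:
        return validate_annotation(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_probes_bed(probes: pd.DataFrame, path) -> None:
    """Probes as BED6; name=probe_id, score=0, strand='.'.

    Background probes carry ``_bg`` appended? No — the flag is encoded in
    the score column (1 for background, 0 otherwise) so the BED round-trips.
    """
    df = probes[["chrom", "start", "end", "probe_id", "is_background"]].copy()
    df["score"] = df.pop("is_background").astype(int)
    df["strand"] = "."
    df[["chrom", "start", "end", "probe_id", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_probes_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6 row")
            chrom, start, end, name, score, _ = parts[:6]
            start, end = int(start), int(end)
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            rows.append((name, chrom, start, end, bool(int(score))))
    df = pd.DataFrame(rows, columns=PROBE_COLUMNS)
    if df["probe_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate probe ids")
    return df


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """Peaks as BED6+2: score = mean log2 ratio ×100 rounded; extra
    columns carry n_probes and fdr_q."""
    df = peaks.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["name"],
            "score": (df["score"] * 100).round().astype(int),
            "strand": ".",
            "n_probes": df["n_probes"],
            "fdr_q": df["fdr_q"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_peaks_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ParseError(f"{path}:{lineno}: expected BED6+2 row")
            chrom, start, end, name, score, _, n_probes, fdr_q = parts[:8]
            start, end = int(start), int(end)
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            rows.append(
                (chrom, start, end, name, int(score) / 100.0, int(n_probes), float(fdr_q))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "n_probes", "fdr_q"]
    )


def write_intensities(intensities: pd.DataFrame, path) -> None:
    """Intensity table TSV: probe_id index, one ``cell:antibody`` column per
    channel."""
    df = intensities.copy()
    df.columns = [f"{c}:{a}" for c, a in df.columns]
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    try:
        cols = [tuple(c.split(":")) for c in df.columns]
        if any(len(c) != 2 for c in cols):
            raise ValueError("columns must be cell:antibody")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = pd.MultiIndex.from_tuples(cols, names=["cell_type", "antibody"])
    if (df.values <= 0).any():
        raise ParseError(f"{path}: non-positive intensity")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    """Expression TSV: gene_id index, one ``cell:replicate`` column each."""
    df = expr.copy()
    df.columns = [f"{c}:{r}" for c, r in df.columns]
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    cols = [tuple(c.split(":")) for c in df.columns]
    if any(len(c) != 2 for c in cols):
        raise ParseError(f"{path}: columns must be cell:replicate")
    df.columns = pd.MultiIndex.from_tuples(cols, names=["cell_type", "replicate"])
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative expression signal")
    return df
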