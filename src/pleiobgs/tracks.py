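"""Stepped genomic tracks: background-selection (B) and recombination maps.

A stepped track is a per-chromosome piecewise-constant function over
0-based half-open segments.  Two value semantics are supported:

* ``B`` -- the background-selection statistic, the expected fraction of
  neutral diversity remaining at a site (1 = no loss to linked selection,
  0 = complete loss).  Distributed maps often scale B to integers 0-1000;
  the reader rescales to [0, 1].
* ``RR`` -- local recombination rate in cM/Mb from a genetic map.

Queries are a point lookup (for SNP positions, 1-based) and a
length-weighted mean over an interval (for genes and regions), computed
over covered bases only, with the coverage fraction reported alongside.

All internal coordinates are 0-based half-open; 1-based inputs (catalog
positions, GFF3) are converted once at the boundary.  The MHC region of
chromosome 6 (25-34 Mb, GRCh37) can be masked out of any point or interval
set, since its unusual diversity and linkage disequilibrium distort both B
and RR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "SteppedTrack",
    "MHC_WINDOW",
    "read_bedgraph",
    "read_genetic_map",
    "read_gene_intervals",
    "mhc_mask",
    "annotate",
]

#: chromosome, first and last masked base (1-based, inclusive)
MHC_WINDOW = ("6", 25_000_000, 34_000_000)

#: floor applied to recombination rates before taking log10 (cM/Mb)
RR_LOG_FLOOR = 1e-3


@dataclass
class SteppedTrack:
    """Piecewise-constant genomic value function.

    ``segments`` maps chromosome label to ``(starts, ends, values)`` arrays
    of equal length, sorted by start, non-overlapping; coordinates are
    0-based half-open.
    """

    kind: str
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, kind: str, df: pd.DataFrame, source: str = "<memory>") -> "SteppedTrack":
        """Build from a DataFrame with chrom/start/end/value (+ optional line)."""
        track = cls(kind=kind)
        lines = df["line"] if "line" in df else pd.Series(np.arange(len(df)) + 1, index=df.index)
        for chrom, grp in df.groupby("chrom", sort=True):
            order = np.argsort(grp["start"].to_numpy(), kind="stable")
            starts = grp["start"].to_numpy(dtype=np.int64)[order]
            ends = grp["end"].to_numpy(dtype=np.int64)[order]
            values = grp["value"].to_numpy(dtype=float)[order]
            lns = lines.to_numpy()[order]
            if np.any(starts >= ends):
                bad = lns[np.argmax(starts >= ends)]
                raise FormatError(f"{source}: empty or inverted segment at line {bad}")
            overlap = starts[1:] < ends[:-1]
            if np.any(overlap):
                bad = lns[1:][overlap][0]
                raise FormatError(f"{source}: overlapping segments at line {bad}")
            track.segments[str(chrom)] = (starts, ends, values)
        return track

    def chromosomes(self) -> list[str]:
        return sorted(self.segments)

    def point_value(self, chrom: str, pos: int) -> float:
        """Track value at a 1-based position; NaN where uncovered."""
        seg = self.segments.get(str(chrom))
        if seg is None:
            return math.nan
        starts, ends, values = seg
        p0 = int(pos) - 1
        idx = int(np.searchsorted(starts, p0, side="right")) - 1
        if idx < 0 or p0 >= ends[idx]:
            return math.nan
        return float(values[idx])

    def point_values(self, chroms, positions) -> np.ndarray:
        return np.array([self.point_value(c, p) for c, p in zip(chroms, positions)])

    def interval_mean(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """Length-weighted mean over a 0-based half-open interval.

        Returns ``(mean, coverage_fraction)``; the mean is NaN when no base
        of the interval is covered.  Uncovered bases are excluded from the
        mean, not imputed.
        """
        if start >= end:
            raise ConfigurationError(f"invalid interval [{start}, {end})")
        seg = self.segments.get(str(chrom))
        if seg is None:
            return math.nan, 0.0
        starts, ends, values = seg
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i0 >= i1:
            return math.nan, 0.0
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        total = float(ov.sum())
        if total <= 0:
            return math.nan, 0.0
        mean = float((ov * values[i0:i1]).sum() / total)
        return mean, total / (end - start)

    def genome_mean(self) -> float:
        """Length-weighted mean value over every covered base."""
        num = den = 0.0
        for starts, ends, values in self.segments.values():
            lens = (ends - starts).astype(float)
            num += float((lens * values).sum())
            den += float(lens.sum())
        return num / den if den else math.nan


def _numeric_or_line_error(series: pd.Series, lines: pd.Series, source: str, what: str):
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() & series.notna()
    if bad.any():
        raise FormatError(f"{source}: non-numeric {what} at line {int(lines[bad].iloc[0])}")
    ok = vals.notna()
    exact = vals.astype(float)
    if ok.any():
        # re-parse through numpy's correctly rounded strtod for exact round trips
        exact[ok] = series[ok].to_numpy(dtype=str).astype(np.float64)
    return exact


def read_bedgraph(path, value_kind: str = "B", b_scale: float | None = None) -> SteppedTrack:
    """Read a 4-column bedGraph-like track (chrom, start, end, value).

    Input need not be sorted.  For ``value_kind="B"`` the scale is
    auto-detected when ``b_scale`` is None: a maximum value above 1 implies
    an integer-scaled map (divisor 1000), otherwise unit scale.  Values must
    land in [0, 1] after scaling.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype=str)
    df["line"] = np.arange(len(df)) + 1
    for col in ("start", "end"):
        df[col] = _numeric_or_line_error(df[col], df["line"], str(path), col).astype("Int64")
    df["value"] = _numeric_or_line_error(df["value"], df["line"], str(path), "value")
    if df[["start", "end", "value"]].isna().any().any():
        raise FormatError(f"{path}: missing field")
    from .catalog import normalize_chrom
    df["chrom"] = normalize_chrom(df["chrom"])
    if value_kind == "B":
        if b_scale is None:
            b_scale = 1000.0 if float(df["value"].max()) > 1.0 else 1.0
        df["value"] = df["value"] / b_scale
        if (df["value"].lt(0) | df["value"].gt(1)).any():
            bad = int(df.loc[df["value"].lt(0) | df["value"].gt(1), "line"].iloc[0])
            raise FormatError(f"{path}: B value outside [0,1] after scaling at line {bad}")
    elif value_kind == "RR":
        if df["value"].lt(0).any():
            bad = int(df.loc[df["value"].lt(0), "line"].iloc[0])
            raise FormatError(f"{path}: negative recombination rate at line {bad}")
    else:
        raise ConfigurationError(f"unknown track value kind {value_kind!r}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return SteppedTrack.from_frame(value_kind, df, source=str(path))


def read_genetic_map(path) -> SteppedTrack:
    """Read a HapMap-style genetic map into a recombination-rate track.

    Expected columns: chromosome, position (bp), rate (cM/Mb), cumulative
    map (cM); a header line is detected and skipped.  The rate on row *i*
    applies to the half-open interval from its position to the next row's
    position on the same chromosome; the last row only terminates the
    previous interval.  Positions are interpreted as 0-based segment starts.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str, skip_blank_lines=True)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: genetic map needs >=3 columns")
    first = str(df.iloc[0, 1]) if len(df) else ""
    offset = 0
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)
        offset = 1
    df = df.iloc[:, :3]
    df.columns = ["chrom", "pos", "rate"]
    df["line"] = np.arange(len(df)) + 1 + offset
    df["pos"] = _numeric_or_line_error(df["pos"], df["line"], str(path), "position").astype(np.int64)
    df["rate"] = _numeric_or_line_error(df["rate"], df["line"], str(path), "rate")
    from .catalog import normalize_chrom
    df["chrom"] = normalize_chrom(df["chrom"])

    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            bad = int(grp["line"].to_numpy()[1:][np.diff(pos) <= 0][0])
            raise FormatError(f"{path}: non-ascending positions at line {bad}")
        if len(pos) < 2:
            warnings.warn(f"{path}: chromosome {chrom} has a single map row; no segments")
            continue
        rates = grp["rate"].to_numpy(dtype=float)
        for s, e, r in zip(pos[:-1], pos[1:], rates[:-1]):
            rows.append((chrom, int(s), int(e), float(r)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SteppedTrack.from_frame("RR", frame, source=str(path))


def read_gene_intervals(path, fmt: str = "bed") -> pd.DataFrame:
    """Read gene coordinates from BED4 (0-based) or GFF3 (1-based, genes only).

    Returns a DataFrame with columns chrom/start/end/label in 0-based
    half-open coordinates.  Duplicate gene names are resolved to the union
    span of their occurrences, with a warning.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        if df.shape[1] < 4:
            raise FormatError(f"{path}: BED gene file needs 4 columns")
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "label"]
        df["line"] = np.arange(len(df)) + 1
        for col in ("start", "end"):
            df[col] = _numeric_or_line_error(df[col], df["line"], str(path), col)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = int(df.loc[df["start"] >= df["end"], "line"].iloc[0])
            raise FormatError(f"{path}: malformed coordinates at line {bad}")
    elif fmt == "gff3":
        from gffutils.iterators import DataIterator
        rows = []
        try:
            for feat in DataIterator(str(path)):
                if feat.featuretype != "gene":
                    continue
                name = (feat.attributes.get("Name") or feat.attributes.get("ID")
                        or feat.attributes.get("gene_id") or [feat.id])[0]
                rows.append((feat.seqid, int(feat.start) - 1, int(feat.end), name))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: malformed GFF3 record: {exc}")
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        if (df["start"] >= df["end"]).any():
            raise FormatError(f"{path}: malformed gene coordinates in GFF3")
    else:
        raise ConfigurationError(f"unknown gene interval format {fmt!r}")
    from .catalog import normalize_chrom
    df["chrom"] = normalize_chrom(df["chrom"]).astype(str)

    dup = df["label"].duplicated(keep=False)
    if dup.any():
        warnings.warn(f"{path}: duplicate gene names merged to union spans: "
                      + ", ".join(sorted(set(df.loc[dup, 'label']))[:5]))
        df = (df.groupby("label", sort=False)
                .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
                .reset_index())
    return df[["chrom", "start", "end", "label"]].reset_index(drop=True)


def mhc_mask(items: pd.DataFrame, window=MHC_WINDOW) -> tuple[pd.DataFrame, int]:
    """Remove items falling in (points) or overlapping (intervals) the MHC.

    Points (a ``pos`` column, 1-based) are removed when contained in the
    window; intervals (``start``/``end``, 0-based half-open) are removed on
    any overlap -- the conservative reading of "located in, or strongly
    linked to" the region.  Idempotent.  Returns (survivors, n_removed).
    """
    chrom, lo, hi = window
    on_chrom = items["chrom"].astype(str) == str(chrom)
    if "pos" in items.columns and "start" not in items.columns:
        inside = on_chrom & items["pos"].ge(lo) & items["pos"].le(hi)
    elif {"start", "end"} <= set(items.columns):
        # window in 0-based half-open coordinates: [lo-1, hi)
        inside = on_chrom & items["start"].lt(hi) & items["end"].gt(lo - 1)
    else:
        raise ConfigurationError("items need either a 'pos' or 'start'/'end' columns")
    kept = items[~inside].reset_index(drop=True)
    return kept, int(inside.sum())


def annotate(
    items: pd.DataFrame,
    b_track: SteppedTrack,
    rr_track: SteppedTrack,
    level: str = "gene",
    genes: pd.DataFrame | None = None,
    rr_floor: float = RR_LOG_FLOOR,
) -> pd.DataFrame:
    """Attach B, RR and log10(RR) to SNPs, genes or regions.

    * ``level="snp"``: items need chrom + pos (1-based); point lookups.
    * ``level="gene"``: items need ``locus_id``; coordinates come from the
      ``genes`` table (label -> span); loci without a matching gene interval
      (intergenic labels) are flagged incomplete.
    * ``level="region"``: items need chrom + start/end (0-based half-open).

    Interval levels use length-weighted means with coverage fractions.
    ``log10RR`` floors the rate at ``rr_floor`` cM/Mb before the log, since
    zero-rate segments would otherwise be undefined.  Rows with missing B or
    RR have ``complete=False`` and are meant to be excluded from regression.
    """
    out = items.copy().reset_index(drop=True)
    if level == "snp":
        if not {"chrom", "pos"} <= set(out.columns):
            raise ConfigurationError("snp-level annotation needs chrom and pos columns")
        out["B"] = b_track.point_values(out["chrom"].astype(str), out["pos"])
        out["RR"] = rr_track.point_values(out["chrom"].astype(str), out["pos"])
        out["b_coverage"] = np.where(np.isnan(out["B"]), 0.0, 1.0)
        out["rr_coverage"] = np.where(np.isnan(out["RR"]), 0.0, 1.0)
    elif level in ("gene", "region"):
        if level == "gene":
            if genes is None:
                raise ConfigurationError("gene-level annotation requires a gene interval table")
            lookup = genes.set_index("label")
            spans = out["locus_id"].map(
                lambda g: tuple(lookup.loc[g, ["chrom", "start", "end"]]) if g in lookup.index else None)
            coords = pd.DataFrame(
                [s if s is not None else (None, -1, -1) for s in spans],
                columns=["span_chrom", "span_start", "span_end"])
            out = pd.concat([out, coords], axis=1)
            cols = ("span_chrom", "span_start", "span_end")
        else:
            if not {"chrom", "start", "end"} <= set(out.columns):
                raise ConfigurationError("region-level annotation needs chrom/start/end columns")
            cols = ("chrom", "start", "end")
        b, rr, bc, rc = [], [], [], []
        for c, s, e in out[list(cols)].itertuples(index=False):
            if c is None or s < 0:
                b.append(math.nan); rr.append(math.nan); bc.append(0.0); rc.append(0.0)
                continue
            bv, bcov = b_track.interval_mean(str(c), int(s), int(e))
            rv, rcov = rr_track.interval_mean(str(c), int(s), int(e))
            b.append(bv); rr.append(rv); bc.append(bcov); rc.append(rcov)
        out["B"] = b
        out["RR"] = rr
        out["b_coverage"] = bc
        out["rr_coverage"] = rc
    else:
        raise ConfigurationError(f"unknown annotation level {level!r}")
    with np.errstate(invalid="ignore"):
        out["log10RR"] = np.log10(np.maximum(out["RR"].to_numpy(dtype=float), rr_floor))
    out["complete"] = out["B"].notna() & out["RR"].notna()
    return out
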