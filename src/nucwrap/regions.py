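"""Genomic-interval layer: CGI x NMI classification, representative
windows, CpG-count stratification, sliding-window scans, score tracks.

All coordinates are 0-based half-open (BED semantics).  The four-way
classification of the genome is A = CGI intersect NMI, B = NMI minus
CGI, C = CGI minus NMI, D = universe minus (CGI union NMI): CpG islands
(CGI) are computationally predicted CpG-rich regions, non-methylated
islands (NMI) are experimentally identified unmethylated regions, and
the two annotations disagree often enough that all four combinations
carry signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqops import ModSequence, count_cpg

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "CPG_BINS",
    "classify_regions",
    "central_window",
    "central_windows",
    "group_by_cpg_count",
    "ensemble_stats",
    "scan_windows",
    "attach_scores",
    "read_bed",
    "write_bed",
    "read_bedgraph",
]

#: CpG-count strata used throughout the ensemble analyses (inclusive).
CPG_BINS = ((0, 4), (5, 14), (15, 24), (25, 34))


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def _to_pyranges(regions):
    import pyranges as pr

    df = pd.DataFrame({
        "Chromosome": [r.chrom for r in regions],
        "Start": [r.start for r in regions],
        "End": [r.end for r in regions],
    })
    if df.empty:
        df = pd.DataFrame({"Chromosome": pd.Series(dtype=str),
                           "Start": pd.Series(dtype=int),
                           "End": pd.Series(dtype=int)})
    return pr.PyRanges(df)


def _from_pyranges(gr, label=None) -> list[GenomicRegion]:
    out = []
    df = gr.df if hasattr(gr, "df") else gr
    if df is None or len(df) == 0:
        return out
    df = df.sort_values(["Chromosome", "Start"])
    for i, row in enumerate(df.itertuples(index=False)):
        name = f"{label}{i + 1}" if label else None
        out.append(GenomicRegion(str(row.Chromosome), int(row.Start),
                                 int(row.End), name))
    return out


def classify_regions(cgi, nmi, universe) -> dict[str, list[GenomicRegion]]:
    """Four-way CGI x NMI partition of the universe.

    Returns ``{"A": CGI&NMI, "B": NMI-CGI, "C": CGI-NMI, "D": universe -
    (CGI|NMI)}``; inputs are merged per chromosome first, outputs are
    pairwise disjoint and together cover the universe's share of
    CGI|NMI plus D.
    """
    import pyranges as pr

    cgi_m = _to_pyranges(cgi).merge()
    nmi_m = _to_pyranges(nmi).merge()
    uni_m = _to_pyranges(universe).merge()
    a = cgi_m.intersect(nmi_m)
    b = nmi_m.subtract(cgi_m)
    c = cgi_m.subtract(nmi_m)
    both = pr.concat([cgi_m, nmi_m]).merge()
    d = uni_m.subtract(both)
    return {"A": _from_pyranges(a, "A"), "B": _from_pyranges(b, "B"),
            "C": _from_pyranges(c, "C"), "D": _from_pyranges(d, "D")}


def central_window(region: GenomicRegion, width: int = 147) -> GenomicRegion | None:
    """Central width-bp window of a region; None (logged) if too short."""
    if len(region) < width:
        logger.warning("region %s:%d-%d shorter than %d bp; skipped",
                       region.chrom, region.start, region.end, width)
        return None
    start = region.start + (len(region) - width) // 2
    return GenomicRegion(region.chrom, start, start + width, region.name)


def central_windows(regions, width: int = 147) -> list[GenomicRegion]:
    out = [central_window(r, width) for r in regions]
    return [r for r in out if r is not None]


def group_by_cpg_count(seqs) -> dict:
    """Partition sequences into the CpG-count bins plus an overflow
    bucket (counts above the last bin are reported, never dropped)."""
    groups = {bins: [] for bins in CPG_BINS}
    groups["overflow"] = []
    for seq in seqs:
        c = count_cpg(seq)
        for lo, hi in CPG_BINS:
            if lo <= c <= hi:
                groups[(lo, hi)].append(seq)
                break
        else:
            groups["overflow"].append(seq)
    return groups


def ensemble_stats(values, groups) -> pd.DataFrame:
    """Per-group n, mean and sample standard deviation of scalar values.

    ``values`` and ``groups`` are parallel sequences; empty groups in the
    output are reported with n = 0 and missing statistics.
    """
    df = pd.DataFrame({"group": list(groups), "value": list(values)})
    rows = []
    for g, sub in df.groupby("group", sort=False):
        v = sub["value"].astype(float)
        rows.append({"group": g, "n": len(v), "mean": v.mean(),
                     "sd": v.std(ddof=1) if len(v) > 1 else (0.0 if len(v) == 1 else np.nan)})
    return pd.DataFrame(rows)


class scan_windows:
    """Iterator over all width-bp windows at a given step (default 1 bp).

    Yields ``(offset, ModSequence)`` where offset is the window start
    relative to the input (plus ``origin``).  Windows containing
    non-A/C/G/T letters are skipped and counted in ``self.skipped``;
    an input shorter than the width yields nothing (with a warning).
    """

    def __init__(self, sequence, width: int = 147, step: int = 1,
                 origin: int = 0):
        self.text = sequence.bases if isinstance(sequence, ModSequence) \
            else str(sequence).upper()
        self.width = int(width)
        self.step = int(step)
        self.origin = int(origin)
        self.skipped = 0
        if len(self.text) < self.width:
            logger.warning("input shorter than window width; empty scan")

    def __iter__(self):
        ok = frozenset("ACGT")
        for start in range(0, len(self.text) - self.width + 1, self.step):
            sub = self.text[start : start + self.width]
            if set(sub) - ok:
                self.skipped += 1
                continue
            yield self.origin + start, ModSequence(sub)

    def __len__(self) -> int:
        return max(0, (len(self.text) - self.width) // self.step + 1)


def read_bed(path) -> list[GenomicRegion]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else None
        out.append(GenomicRegion(str(row[0]), int(row[1]), int(row[2]), name))
    return out


def write_bed(regions, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = f"\t{r.name}" if r.name else ""
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}{name}\n")


def read_bedgraph(path) -> dict:
    """Per-bp score track: {chrom: (starts, ends, values)} sorted arrays."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    track = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        track[str(chrom)] = (sub["start"].to_numpy(int),
                             sub["end"].to_numpy(int),
                             sub["value"].to_numpy(float))
    return track


def attach_scores(items, track: dict, flag_threshold: float = 0.5) -> pd.DataFrame:
    """Mean per-bp track score over each region.

    Items with more than ``flag_threshold`` of their span uncovered are
    flagged; a chromosome absent from the track is an error.
    """
    rows = []
    for r in items:
        if r.chrom not in track:
            raise ValueError(f"track has no chromosome {r.chrom!r}")
        starts, ends, values = track[r.chrom]
        total = 0.0
        covered = 0
        lo = np.searchsorted(ends, r.start, side="right")
        for i in range(lo, len(starts)):
            if starts[i] >= r.end:
                break
            ov = min(ends[i], r.end) - max(starts[i], r.start)
            if ov > 0:
                total += values[i] * ov
                covered += ov
        span = len(r)
        frac = covered / span
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "mean_score": total / covered if covered else np.nan,
            "covered_fraction": frac,
            "flagged": frac < flag_threshold,
        })
    return pd.DataFrame(rows)
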