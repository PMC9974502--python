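"""Chromosome-level summary statistics.

Small, sharply defined quantities used to characterise chromosome classes:

* **tau** — the tissue-specificity index of expression breadth,
  ``tau = sum_i (1 - x_i / x_max) / (n - 1)`` over ``n`` tissues: 0 for a
  uniformly expressed (housekeeping-like) gene, 1 for strict single-tissue
  expression.
* **interchromosomal Hi-C contact enrichment** — observed trans contacts per
  chromosome pair against a marginal-product expectation,
  ``E_ab = T_a T_b / sum_c T_c`` on trans totals, rescaled so the expected
  matrix conserves the observed trans total, then log2(O/E).  Pericentromeric
  bins can be masked out first so the statistic reflects euchromatin only.
* **relative ChIP level** — mean ChIP/input ratio over windows annotated
  with a repeat class divided by the mean over unique-sequence windows.
* **amplicon expression** — mean read count across the copies of a multicopy
  gene family normalised by the summed mRNA length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import KaryoevoError, TableFormatError


# ---------------------------------------------------------------------------
# expression breadth
# ---------------------------------------------------------------------------

def tau(expression: pd.DataFrame, log_transform: bool = False) -> pd.Series:
    """Per-gene tau in [0, 1] from a genes x tissues expression matrix.

    Values are linear TPM-scale by default; ``log_transform`` applies
    log2(x + 1) first.  Genes with zero expression everywhere are undefined,
    excluded from the result, and reported via a warning.
    """
    if expression.shape[1] < 2:
        raise KaryoevoError("tau needs at least two tissues")
    if (expression.values < 0).any():
        raise KaryoevoError("expression values must be non-negative")
    x = expression.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max(axis=1)
    valid = xmax > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"tau: excluded {n_dropped} gene(s) with all-zero "
                      "expression", stacklevel=2)
    x = x.loc[valid]
    ratios = x.div(x.max(axis=1), axis=0)
    n = x.shape[1]
    return (1.0 - ratios).sum(axis=1) / (n - 1)


# ---------------------------------------------------------------------------
# Hi-C trans-contact enrichment
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Binned, symmetric Hi-C contact counts.

    ``bins`` has one row per genomic bin (columns chrom, index, start, plus
    a boolean ``masked`` flag for pericentromeric bins); ``contacts`` is a
    sparse upper-triangle-or-full listing (bin_i, bin_j, count) indexing
    rows of ``bins``.  Duplicate and mirrored entries are accumulated.
    """

    bins: pd.DataFrame
    contacts: pd.DataFrame
    bin_size: int = 40_000

    def __post_init__(self):
        bins = self.bins.reset_index(drop=True)
        if "masked" not in bins.columns:
            bins = bins.assign(masked=False)
        self.bins = bins
        c = self.contacts.reset_index(drop=True)
        if (c["count"] < 0).any():
            raise TableFormatError("contact counts must be non-negative")
        n = len(bins)
        if len(c) and (c[["bin_i", "bin_j"]].values >= n).any():
            raise TableFormatError("contact bin index out of range")
        # fold to unordered pairs so the matrix is symmetric by construction
        lo = c[["bin_i", "bin_j"]].min(axis=1)
        hi = c[["bin_i", "bin_j"]].max(axis=1)
        self.contacts = (pd.DataFrame({"bin_i": lo, "bin_j": hi,
                                       "count": c["count"].astype(float)})
                         .groupby(["bin_i", "bin_j"], as_index=False)["count"]
                         .sum())

    @classmethod
    def read(cls, bins_path: str | Path, contacts_path: str | Path,
             bin_size: int = 40_000) -> "ContactMatrix":
        """Read the 3-column sparse text dump plus the bin table."""
        bins = pd.read_csv(bins_path, sep="\t",
                           names=["chrom", "index", "start"], dtype={0: str})
        try:
            contacts = pd.read_csv(contacts_path, sep="\t",
                                   names=["bin_i", "bin_j", "count"])
        except pd.errors.EmptyDataError:
            contacts = pd.DataFrame(columns=["bin_i", "bin_j", "count"])
        return cls(bins, contacts, bin_size=bin_size)

    def mask_from_bed(self, bed_path: str | Path) -> None:
        """Mark bins overlapping any interval of a BED file as masked
        (pericentromeric heterochromatin exclusion)."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        with Path(bed_path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.setdefault(chrom, []).append((int(start), int(end)))
        masked = self.bins["masked"].to_numpy(copy=True)
        for idx, row in self.bins.iterrows():
            b0 = int(row["start"])
            b1 = b0 + self.bin_size
            for s, e in intervals.get(row["chrom"], ()):
                if s < b1 and b0 < e:
                    masked[idx] = True
                    break
        self.bins["masked"] = masked


def contact_enrichment(matrix: ContactMatrix,
                       exclude_pch: bool = True) -> pd.DataFrame:
    """Observed/expected trans-contact enrichment per chromosome pair.

    For chromosomes a, b the observed value O_ab sums the contacts between
    their (unmasked) bins; the expectation is the marginal product on trans
    totals, E_ab = T_a T_b / sum_c T_c, rescaled so that sum E = sum O over
    all trans pairs.  Returns one row per unordered chromosome pair with
    columns observed, expected, log2_ratio; pairs involving a chromosome
    without trans contacts are reported with undefined (NaN) expectation.
    """
    bins = matrix.bins
    chroms = sorted(bins["chrom"].unique())
    if len(chroms) < 2:
        raise KaryoevoError("contact enrichment needs at least 2 chromosomes")
    keep = ~bins["masked"] if exclude_pch else pd.Series(True, index=bins.index)
    chrom_of = bins["chrom"]
    c = matrix.contacts
    ci = c["bin_i"].map(chrom_of)
    cj = c["bin_j"].map(chrom_of)
    ok = (c["bin_i"].map(keep) & c["bin_j"].map(keep) & (ci != cj))
    trans = pd.DataFrame({
        "chrom_a": np.minimum(ci[ok], cj[ok]),
        "chrom_b": np.maximum(ci[ok], cj[ok]),
        "count": c.loc[ok, "count"]})
    observed = trans.groupby(["chrom_a", "chrom_b"])["count"].sum()
    total_obs = float(observed.sum())
    if total_obs <= 0:
        raise KaryoevoError("no trans contacts to normalise against")

    totals = {ch: 0.0 for ch in chroms}
    for (a, b), o in observed.items():
        totals[a] += o
        totals[b] += o
    s = sum(totals.values())

    rows = []
    raw_sum = sum(totals[a] * totals[b] / s
                  for i, a in enumerate(chroms) for b in chroms[i + 1:]
                  if totals[a] > 0 and totals[b] > 0)
    scale = total_obs / raw_sum if raw_sum > 0 else float("nan")
    for i, a in enumerate(chroms):
        for b in chroms[i + 1:]:
            o = float(observed.get((a, b), 0.0))
            if totals[a] <= 0 or totals[b] <= 0:
                rows.append((a, b, o, np.nan, np.nan))
                continue
            e = totals[a] * totals[b] / s * scale
            with np.errstate(divide="ignore"):
                ratio = np.log2(o / e) if e > 0 else np.nan
            rows.append((a, b, o, e, ratio))
    return pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "observed",
                                       "expected", "log2_ratio"])


# ---------------------------------------------------------------------------
# ChIP windows and amplicons
# ---------------------------------------------------------------------------

UNIQUE_ANNOTATION = "unique"


def validate_chip_track(track: pd.DataFrame) -> None:
    """Check ratio non-negativity and per-chromosome window disjointness."""
    if (track["ratio"] < 0).any():
        raise TableFormatError("ChIP/input ratios must be non-negative")
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["end"].shift() > sub["start"]).fillna(False).any():
            raise TableFormatError(f"overlapping windows on {chrom}")


def relative_chip_level(track: pd.DataFrame, repeat_class: str) -> float:
    """Mean ChIP/input over a repeat class divided by the unique-sequence
    mean.  ``track`` needs columns chrom, start, end, ratio, annotation."""
    validate_chip_track(track)
    repeat = track.loc[track["annotation"] == repeat_class, "ratio"]
    unique = track.loc[track["annotation"] == UNIQUE_ANNOTATION, "ratio"]
    if repeat.empty:
        raise KaryoevoError(f"no windows annotated {repeat_class!r}")
    if unique.empty:
        raise KaryoevoError("no unique-sequence windows")
    unique_mean = float(unique.mean())
    if unique_mean == 0:
        raise KaryoevoError("unique-sequence mean ratio is zero")
    return float(repeat.mean()) / unique_mean


def amplicon_expression(read_counts: Sequence[float],
                        mrna_lengths: Sequence[float]) -> float:
    """Mean read count across a gene family's copies, normalised by the
    total mRNA length of those copies."""
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(mrna_lengths, dtype=float)
    if counts.size == 0 or lengths.size == 0:
        raise KaryoevoError("amplicon expression needs at least one copy")
    if (lengths <= 0).any():
        raise KaryoevoError("mRNA lengths must be positive")
    return float(counts.mean() / lengths.sum())
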