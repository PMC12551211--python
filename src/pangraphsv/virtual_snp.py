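"""Deletion-to-"virtual SNP" conversion and marker informativeness.

A deletion can be genotyped on a standard SNP array by exploiting the base
change at its breakpoints: if the first nucleotide of the deleted region
differs from the first nucleotide immediately after the 3' breakpoint, the
deleted-region base is the reference allele of the virtual SNP and the
post-breakpoint base is its alternative allele.  The same test on the
opposite strand (comparing the last deleted base with the base immediately
before the 5' breakpoint) serves as an independent confirmation; both
flags are reported and the caller decides how to filter.

Coordinates here are 1-based inclusive [s, e] to match breakpoint prose;
:func:`from_half_open` converts from the pipeline's internal convention.

Marker informativeness uses the standard single-locus statistics: with
allele frequencies p and q = 1 - p, expected heterozygosity He = 2pq and
polymorphic information content PIC = He - 2 p^2 q^2; both peak at
p = 0.5 (He = 0.500, PIC = 0.375).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pangraphsv")

_VALID = set("ACGT")


@dataclass
class VirtualSNP:
    """Breakpoint base-change proxy for a deletion."""

    sv_id: str
    chromosome: str
    s: int                      # first deleted base, 1-based inclusive
    e: int                      # last deleted base, 1-based inclusive
    ref_allele: str | None      # base at s
    alt_allele: str | None      # base at e + 1
    forward_convertible: bool
    reverse_confirmed: bool
    reason: str | None = None   # set when not convertible

    @property
    def convertible(self) -> bool:
        return self.forward_convertible


def from_half_open(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive [s, e]."""
    if end <= start:
        raise ValueError("empty interval has no deleted bases")
    return start + 1, end


def convert_deletion(ref_seq: str, interval: tuple[int, int],
                     chromosome: str = "ref", sv_id: str = "sv") -> VirtualSNP:
    """Apply the breakpoint base-change test to a deletion [s, e].

    Forward test: base(s) vs base(e+1); reverse (opposite-strand) test:
    base(e) vs base(s-1).  The conversion is strand-mirror invariant: the
    forward test of the reverse-complemented sequence with mirrored
    coordinates equals the reverse test of the original.

    Deletions touching the sequence ends, or with an ambiguity code at a
    tested position, are reported not-convertible with a reason.
    """
    s, e = interval
    n = len(ref_seq)
    if not (1 <= s <= e <= n):
        raise ValueError(f"interval [{s},{e}] outside sequence of length {n}")

    def fail(reason: str) -> VirtualSNP:
        return VirtualSNP(sv_id=sv_id, chromosome=chromosome, s=s, e=e,
                          ref_allele=None, alt_allele=None,
                          forward_convertible=False, reverse_confirmed=False,
                          reason=reason)

    if s == 1 or e == n:
        return fail("deletion touches sequence end; flanking base missing")
    first_del = ref_seq[s - 1].upper()        # first deleted base
    after_3p = ref_seq[e].upper()             # first base after 3' breakpoint
    last_del = ref_seq[e - 1].upper()         # last deleted base
    before_5p = ref_seq[s - 2].upper()        # base before 5' breakpoint
    if {first_del, after_3p, last_del, before_5p} - _VALID:
        return fail("ambiguity base at a tested position")

    forward = first_del != after_3p
    reverse = last_del != before_5p
    return VirtualSNP(
        sv_id=sv_id, chromosome=chromosome, s=s, e=e,
        ref_allele=first_del if forward else None,
        alt_allele=after_3p if forward else None,
        forward_convertible=forward, reverse_confirmed=reverse)


def inclusive_span(s: int, e: int) -> int:
    """Length in bp of a 1-based inclusive interval [s, e]."""
    if e < s:
        raise ValueError("end before start")
    return e - s + 1


# ---------------------------------------------------------------------------
# Marker statistics
# ---------------------------------------------------------------------------

@dataclass
class MarkerStats:
    marker_id: str
    p: float            # frequency of the reference allele
    q: float
    maf: float
    he: float
    pic: float
    monomorphic: bool
    n_called: int


def marker_stats(dosages: Sequence[float] | np.ndarray,
                 marker_id: str = "marker") -> MarkerStats:
    """He/PIC/MAF from a 0/1/2 dosage vector (NaN = missing call).

    Frequencies are allele counts over non-missing calls; a monomorphic
    marker (one allele absent) is flagged and has He = PIC = 0.
    """
    x = np.asarray(dosages, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("all genotype calls missing")
    q = float(x.sum()) / (2.0 * x.size)   # alternative-allele frequency
    p = 1.0 - q
    he = 2.0 * p * q
    pic = he - 2.0 * p * p * q * q
    return MarkerStats(marker_id=marker_id, p=p, q=q, maf=min(p, q),
                       he=he, pic=pic, monomorphic=(p == 0.0 or q == 0.0),
                       n_called=int(x.size))


def panel_summary(dosages: pd.DataFrame,
                  breed_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Mean MAF/He/PIC per breed and overall, polymorphic markers only.

    ``dosages``: samples x markers frame.  A marker counts as polymorphic
    when both alleles are observed at least once in the full genotyped
    set.  Rows: one per breed plus "overall"; columns: n_markers,
    n_polymorphic, n_monomorphic, mean_maf, mean_he, mean_pic.  Breeds
    with no genotyped animals are excluded (logged).
    """
    overall = {m: marker_stats(dosages[m].to_numpy(), m) for m in dosages.columns}
    polymorphic = [m for m, st in overall.items() if not st.monomorphic]

    def row(frame: pd.DataFrame) -> dict[str, float]:
        stats = [marker_stats(frame[m].to_numpy(), m) for m in polymorphic
                 if frame[m].notna().any()]
        return {
            "n_markers": len(overall),
            "n_polymorphic": len(polymorphic),
            "n_monomorphic": len(overall) - len(polymorphic),
            "mean_maf": float(np.mean([s.maf for s in stats])) if stats else np.nan,
            "mean_he": float(np.mean([s.he for s in stats])) if stats else np.nan,
            "mean_pic": float(np.mean([s.pic for s in stats])) if stats else np.nan,
        }

    rows = {"overall": row(dosages)}
    if breed_map is not None:
        breeds: dict[str, list[str]] = {}
        for sample, breed in breed_map.items():
            breeds.setdefault(breed, []).append(sample)
        for breed in sorted(breeds):
            members = [s for s in breeds[breed] if s in dosages.index]
            if not members:
                logger.warning("breed %s has no genotyped animals; excluded", breed)
                continue
            rows[breed] = row(dosages.loc[members])
    return pd.DataFrame(rows).T


def stats_table(dosages: pd.DataFrame) -> pd.DataFrame:
    """Per-marker statistics frame (al_maf-style columns)."""
    recs = []
    for m in dosages.columns:
        st = marker_stats(dosages[m].to_numpy(), m)
        recs.append({"marker_id": m, "p": st.p, "q": st.q, "freq_maf": st.maf,
                     "He": st.he, "PIC": st.pic, "monomorphic": st.monomorphic,
                     "n_called": st.n_called})
    return pd.DataFrame(recs)
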