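"""Curation of candidate de novo insertions into confirmed retrotranspositions.

A genuine Ty1 retrotransposition leaves a 5-6 nt target-site duplication
(TSD): the staggered double-strand cut of the integrase duplicates the host
bases flanking the new copy as an exact direct repeat. Candidates emitted by
SV classification are therefore confirmed only when (1) an exact 5- or 6-nt
TSD is detectable at their junctions, (2) the reconstructed junction (flank
context with the doubled TSD) occurs nowhere in the parental genomes — a
junction already present in a parent marks a pre-existing locus, not a new
insertion — and (3) the TSD motif is absent from the TSD set of all
parental full-length copies. Every rejection records exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import seq_to_str

__all__ = [
    "TSD",
    "find_tsd",
    "uniqueness_filters",
    "curate_candidates",
    "insertion_statistics",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class TSD:
    """An exact direct repeat flanking an insertion."""

    sequence: str
    length: int

    def __post_init__(self) -> None:
        if self.length not in (5, 6) or len(self.sequence) != self.length:
            raise ValueError("TSD must be 5 or 6 exact bases")


def find_tsd(flank5: str, flank3: str) -> TSD | None:
    """Longest exact 5-6 nt direct repeat across an insertion junction.

    Compares the last k bases of the 5' flank with the first k bases of the
    3' flank for k = 6 then k = 5 (longest match wins); returns None when
    neither matches or when the junction bases are not plain ACGT.
    """
    if len(flank5) < 6 or len(flank3) < 6:
        raise ValueError("flanks must be at least 6 bases")
    flank5 = flank5.upper()
    flank3 = flank3.upper()
    for k in (6, 5):
        a, b = flank5[-k:], flank3[:k]
        if not (_DNA.issuperset(a) and _DNA.issuperset(b)):
            return None
        if a == b:
            return TSD(a, k)
    return None


def _junction_string(flank5: str, flank3: str, tsd: TSD, context: int = 20) -> str:
    """Flank context spanning the insertion with its doubled TSD.

    A fresh insertion duplicates the target site, so the evolved locus reads
    ``... X [tsd] <element> [tsd] Y ...`` where the parent has ``... X [tsd]
    Y ...``; the element-free concatenation of both flanks therefore carries
    the TSD twice and occurs in a parental genome only if that genome
    already held an insertion at the site.
    """
    w = context + tsd.length
    return flank5[-w:] + flank3[:w]


def uniqueness_filters(
    candidate: dict,
    parental_genomes: dict,
    parental_tsds,
    other_junctions=None,
    context: int = 20,
) -> tuple[str, str]:
    """Confirm or reject one TSD-bearing candidate.

    ``candidate`` needs keys ``flank5``, ``flank3`` and ``tsd`` (a
    :class:`TSD`). Returns ``(status, reason)`` with status ``confirmed`` or
    ``rejected`` and reason one of ``non_unique_junction``,
    ``non_unique_tsd``, ``shared_junction`` or ``""``.
    """
    if not parental_genomes:
        raise ValueError("at least one parental genome is required")
    tsd = candidate["tsd"]
    junction = _junction_string(candidate["flank5"], candidate["flank3"], tsd, context)
    for genome in parental_genomes.values():
        for chrom_seq in genome.chroms.values():
            if junction in seq_to_str(chrom_seq):
                return "rejected", "non_unique_junction"
    if tsd.sequence in set(parental_tsds):
        return "rejected", "non_unique_tsd"
    if other_junctions and junction in other_junctions:
        return "rejected", "shared_junction"
    return "confirmed", ""


def curate_candidates(
    candidates,
    parental_genomes: dict,
    parental_tsds,
    context: int = 20,
    cross_line_unique: bool = True,
) -> pd.DataFrame:
    """Run the TSD and uniqueness filters over a candidate set.

    ``candidates`` is a sequence of dicts with ``locus_id``, ``line_id``,
    ``flank5``, ``flank3`` (flank sequences exclude the element itself).
    With ``cross_line_unique`` the same junction reappearing in another
    line is rejected on both occurrences (a shared junction is a parental
    polymorphism, not an independent insertion).
    """
    # cache genome strings once
    genome_strs = [
        seq_to_str(chrom_seq)
        for genome in parental_genomes.values()
        for chrom_seq in genome.chroms.values()
    ]
    if not genome_strs:
        raise ValueError("at least one parental genome is required")
    tsd_set = set(parental_tsds)

    prelim = []
    junctions: dict[str, list[int]] = {}
    for i, cand in enumerate(candidates):
        tsd = find_tsd(cand["flank5"], cand["flank3"])
        if tsd is None:
            prelim.append((None, None))
            continue
        j = _junction_string(cand["flank5"], cand["flank3"], tsd, context)
        junctions.setdefault(j, []).append(i)
        prelim.append((tsd, j))

    shared = set()
    if cross_line_unique:
        for j, idxs in junctions.items():
            lines = {candidates[i]["line_id"] for i in idxs}
            if len(lines) > 1:
                shared.add(j)

    rows = []
    for cand, (tsd, junction) in zip(candidates, prelim):
        if tsd is None:
            status, reason = "rejected", "no_tsd"
        elif any(junction in g for g in genome_strs):
            status, reason = "rejected", "non_unique_junction"
        elif tsd.sequence in tsd_set:
            status, reason = "rejected", "non_unique_tsd"
        elif junction in shared:
            status, reason = "rejected", "shared_junction"
        else:
            status, reason = "confirmed", ""
        rows.append(
            dict(
                locus_id=cand["locus_id"],
                line_id=cand.get("line_id", ""),
                family=cand.get("family", ""),
                tsd=tsd.sequence if tsd else "",
                tsd_len=tsd.length if tsd else 0,
                status=status,
                reason=reason,
            )
        )
    return pd.DataFrame(rows)


def insertion_statistics(
    n_confirmed: int,
    n_lines: int,
    generations: float | None = None,
    elements_per_line: float | None = None,
) -> dict:
    """Per-line insertion mean and, when scalable, the per-cross rate.

    The per-line mean is reported to 2 decimals. The per-cross rate divides
    the confirmed count by lines x generations x mean full-length element
    count of the mobilizable family (events per line per generation per
    element).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    out = {"per_line_mean": round(n_confirmed / n_lines, 2)}
    if generations is not None and elements_per_line is not None:
        if generations <= 0 or elements_per_line <= 0:
            raise ValueError("generations and element count must be positive")
        out["per_cross_rate"] = n_confirmed / (
            n_lines * generations * elements_per_line
        )
    return out
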