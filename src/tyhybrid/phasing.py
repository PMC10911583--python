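"""Read classification into parental subgenomes (trio-binning style).

Each long read from a hybrid is assigned to one of the two parental
subgenomes using the informative variants it covers: sites where the two
parents carry different alleles. A read is classified only when it carries
at least two informative observations in total and one parent's support is
at least twice the other's; everything else stays unclassified rather than
being arbitrated by weaker evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["classify_read", "phase_library", "length_bias_summary", "PhasingResult"]

CALLS = ("P1", "P2", "unclassified")


def classify_read(n1: int, n2: int, min_support_mode: str = "total") -> str:
    """Call one read from its per-parent informative-variant counts.

    With ``min_support_mode="total"`` (default) the >=2-variant threshold
    applies to ``n1 + n2``; with ``"winner"`` it applies to the majority
    side alone. Ties and sub-threshold ratios return ``"unclassified"``.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("support counts must be non-negative")
    if min_support_mode == "total":
        if n1 + n2 < 2:
            return "unclassified"
    elif min_support_mode == "winner":
        if max(n1, n2) < 2:
            return "unclassified"
    else:
        raise ValueError(f"unknown min_support_mode {min_support_mode!r}")
    if n1 >= 2 * n2 and n1 > n2:
        return "P1"
    if n2 >= 2 * n1 and n2 > n1:
        return "P2"
    return "unclassified"


@dataclass
class PhasingResult:
    """Per-read calls plus library-level base-weighted summaries."""

    reads: pd.DataFrame  # read_id, call, n1, n2, length[, true_origin]
    percent_bases: dict  # {"P1": float, "P2": float, "unclassified": float}
    base_ratio: float | None  # classified P1:P2 base ratio, None if no P2

    @property
    def classification_rate(self) -> float:
        """Percent of sequenced bases assigned to either subgenome."""
        return self.percent_bases["P1"] + self.percent_bases["P2"]


def phase_library(
    reads,
    variants: pd.DataFrame,
    min_support_mode: str = "total",
) -> PhasingResult:
    """Classify a read library against an informative-variant table.

    ``reads`` is a sequence of objects with ``read_id``, ``length`` and
    ``observed_alleles`` (list of ``(var_id, allele)``); alleles that are
    neither ``P1`` nor ``P2`` (sequencing miscalls) support neither parent.
    """
    known = set(variants["var_id"]) if len(variants) else set()
    rows = []
    for r in reads:
        n1 = n2 = 0
        for var_id, allele in r.observed_alleles:
            if var_id not in known:
                raise ValueError(
                    f"read {r.read_id} references unknown variant {var_id}"
                )
            if allele == "P1":
                n1 += 1
            elif allele == "P2":
                n2 += 1
        call = classify_read(n1, n2, min_support_mode)
        row = [r.read_id, call, n1, n2, r.length]
        rows.append(row)
    df = pd.DataFrame(rows, columns=["read_id", "call", "n1", "n2", "length"])
    origins = [getattr(r, "true_origin", None) for r in reads]
    if any(o is not None for o in origins):
        df["true_origin"] = origins
    total = float(df["length"].sum())
    percent = {}
    for c in CALLS:
        sel = df.loc[df["call"] == c, "length"].sum()
        percent[c] = 100.0 * sel / total if total else 0.0
    b1 = df.loc[df["call"] == "P1", "length"].sum()
    b2 = df.loc[df["call"] == "P2", "length"].sum()
    ratio = float(b1) / float(b2) if b2 else None
    return PhasingResult(reads=df, percent_bases=percent, base_ratio=ratio)


def length_bias_summary(result: PhasingResult) -> pd.DataFrame:
    """Mean/median read length per call class.

    Classes with no reads appear with ``n = 0`` and NaN lengths, so an
    empty unclassified set is visible rather than silently missing.
    """
    df = result.reads
    if df.empty:
        raise ValueError("empty library")
    rows = []
    for c in CALLS:
        lens = df.loc[df["call"] == c, "length"]
        rows.append(
            [
                c,
                len(lens),
                float(lens.mean()) if len(lens) else np.nan,
                float(lens.median()) if len(lens) else np.nan,
            ]
        )
    return pd.DataFrame(rows, columns=["call", "n", "mean_length", "median_length"])
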