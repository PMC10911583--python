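"""Rule-based SV classification of orthologous Ty loci.

For each orthologous Ty cluster in each evolved subgenome, the state of the
locus (annotation content, copy number from depth tracts, assembly presence
from a reverse liftover of the flanking windows) is reduced to Boolean
variables and pushed through a fixed hierarchy of rules:

    no change -> copy-number change (polyploidy / aneuploidy / LOH)
    -> truncation -> excision -> de novo candidate -> deletion
    -> unclassified

Copy-number changes are then sub-classified: genome-wide gains from ploidy
metadata are polyploidy; tracts covering at least 95% of a chromosome are
aneuploidy; tracts with a reciprocal change in the homologous subgenome
over at least half their span are LOH (copy-neutral inter-homolog
conversion); the remainder defaults to segmental aneuploidy.

``cn_delta`` counts full-length copies: ``cn_ma * n_full_ma -
cn_parent * n_full_parent``, which makes the per-line bookkeeping identity
sum(gains) - sum(losses) = net change exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LocusState",
    "SVCall",
    "assembly_presence",
    "consistency_filter",
    "classify_locus",
    "subclassify_cn_change",
    "tally_and_test",
]

CLASS_ORDER = (
    "no_change",
    "cn_change",  # merged polyploidy/aneuploidy/loh before sub-classification
    "truncation",
    "excision",
    "denovo_candidate",
    "deletion",
    "unclassified",
)


@dataclass
class LocusState:
    """Boolean and count variables describing one cluster in one subgenome."""

    cluster_id: str
    line_id: str
    subgenome: str
    chrom: str
    span: tuple  # (start, end) in parental coordinates
    is_complex: bool
    parent_types: tuple = ()  # (family, completeness) multiset, sorted
    ma_types: tuple = ()
    cn_ma: float = 1.0
    cn_parent: float = 1.0
    assembly_present: bool = True
    # explicit Boolean variables; derived from the type multisets when left
    # as None, validated against them when supplied
    parent_has_annotation: bool | None = None
    ma_has_annotation: bool | None = None

    def __post_init__(self) -> None:
        for attr, types in (
            ("parent_has_annotation", self.parent_types),
            ("ma_has_annotation", self.ma_types),
        ):
            derived = len(types) > 0
            given = getattr(self, attr)
            if given is None:
                setattr(self, attr, derived)
            elif given != derived:
                raise ValueError(
                    f"contradictory state for {self.cluster_id}: {attr}="
                    f"{given} but annotation types {tuple(types)}"
                )

    @property
    def same_content(self) -> bool:
        return tuple(sorted(self.parent_types)) == tuple(sorted(self.ma_types))

    @property
    def same_cn(self) -> bool:
        return self.cn_ma == self.cn_parent

    def _n_full(self, types) -> int:
        return sum(1 for _fam, comp in types if comp == "full-length")


@dataclass
class SVCall:
    """SV class assigned to one orthologous Ty locus in one subgenome."""

    cluster_id: str
    line_id: str
    subgenome: str
    sv_class: str
    cn_delta: float = 0.0


def _covered_fraction(blocks: pd.DataFrame, start: int, end: int) -> float:
    if end <= start:
        return 1.0
    if blocks is None or len(blocks) == 0:
        return 0.0
    s = blocks["src_start"].to_numpy()
    e = blocks["src_end"].to_numpy()
    ov = np.clip(np.minimum(e, end) - np.maximum(s, start), 0, None).sum()
    return float(ov) / (end - start)


def assembly_presence(
    span: tuple,
    chrom: str,
    chrom_length: int,
    reverse_liftover: dict,
    flank: int = 500,
    min_covered: float = 0.9,
) -> bool:
    """Whether the evolved assembly still contains the locus neighbourhood.

    The two ``flank``-wide windows immediately flanking the parental span
    (clipped at chromosome ends) must both project into the evolved
    assembly; a window projects when at least ``min_covered`` of it falls
    inside reverse-liftover blocks (small TSD-sized gaps at an excised or
    deleted element must not mask an otherwise intact region). Both flanks
    are required — one mapping flank alone is treated as absent.
    """
    start, end = span
    blocks = reverse_liftover.get(chrom)
    left = (max(start - flank, 0), max(start, 0))
    right = (min(end, chrom_length), min(end + flank, chrom_length))
    return (
        _covered_fraction(blocks, *left) >= min_covered
        and _covered_fraction(blocks, *right) >= min_covered
    )


def consistency_filter(cn_ma: float, present: bool) -> str:
    """Exclude loci whose depth CN and assembly presence contradict."""
    if cn_ma < 0:
        raise ValueError("copy number must be non-negative")
    if cn_ma == 0 and present:
        return "exclude"
    if cn_ma > 0 and not present:
        return "exclude"
    return "keep"


def classify_locus(state: LocusState) -> SVCall:
    """Apply the rule hierarchy to one locus state (already consistency-kept)."""
    n_full_ma = state._n_full(state.ma_types)
    n_full_parent = state._n_full(state.parent_types)
    delta = state.cn_ma * n_full_ma - state.cn_parent * n_full_parent

    def call(sv_class: str, d: float = None) -> SVCall:
        return SVCall(
            cluster_id=state.cluster_id,
            line_id=state.line_id,
            subgenome=state.subgenome,
            sv_class=sv_class,
            cn_delta=delta if d is None else d,
        )

    if state.same_content and state.same_cn:
        return call("no_change", 0.0)
    if not state.same_cn and (
        state.same_content
        or (not state.ma_has_annotation and not state.assembly_present)
    ):
        return call("cn_change")
    parent_full = any(c == "full-length" for _f, c in state.parent_types)
    ma_trunc = any(c == "truncated" for _f, c in state.ma_types)
    ma_solo = any(c == "solo-LTR" for _f, c in state.ma_types)
    if parent_full and ma_trunc and n_full_ma < n_full_parent:
        return call("truncation")
    if parent_full and ma_solo and n_full_ma < n_full_parent:
        return call("excision")
    if n_full_ma == n_full_parent + 1:
        return call("denovo_candidate")
    if (
        state.parent_has_annotation
        and not state.ma_has_annotation
        and state.assembly_present
    ):
        return call("deletion")
    return call("unclassified", 0.0)


def subclassify_cn_change(
    call: SVCall,
    span: tuple,
    chrom: str,
    tracts_self: pd.DataFrame,
    tracts_homolog: pd.DataFrame,
    chrom_length: int,
    ploidy: int,
    whole_chrom_fraction: float = 0.95,
    reciprocal_overlap: float = 0.5,
) -> SVCall:
    """Resolve a merged copy-number-change call into polyploidy/aneuploidy/LOH."""
    if call.sv_class != "cn_change":
        raise ValueError("sub-classification applies to cn_change calls only")
    if tracts_homolog is None or tracts_homolog.empty:
        raise ValueError("homologous subgenome tracts are required")
    if ploidy > 1:
        return SVCall(call.cluster_id, call.line_id, call.subgenome,
                      "polyploidy", call.cn_delta)
    mid = (span[0] + span[1]) // 2
    sel = tracts_self[
        (tracts_self["chrom"] == chrom)
        & (tracts_self["start"] <= mid)
        & (tracts_self["end"] > mid)
    ]
    if sel.empty:
        raise KeyError(f"locus midpoint {chrom}:{mid} outside self tracts")
    tract = sel.iloc[0]
    if (tract.end - tract.start) >= whole_chrom_fraction * chrom_length:
        cls = "aneuploidy"
    else:
        sign = np.sign(tract.level - 1.0)
        hom = tracts_homolog[
            (tracts_homolog["chrom"] == chrom)
            & (tracts_homolog["end"] > tract.start)
            & (tracts_homolog["start"] < tract.end)
            & (np.sign(tracts_homolog["level"] - 1.0) == -sign)
        ]
        ov = 0
        for _, h in hom.iterrows():
            ov += min(h.end, tract.end) - max(h.start, tract.start)
        cls = (
            "loh"
            if ov >= reciprocal_overlap * (tract.end - tract.start)
            else "aneuploidy"
        )
    return SVCall(call.cluster_id, call.line_id, call.subgenome, cls, call.cn_delta)


def tally_and_test(
    calls: pd.DataFrame,
    size_changes: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-line gain/loss tallies and per-cross tests of net CN change.

    Parameters
    ----------
    calls : DataFrame
        Columns line_id, subgenome, cross, sv_class, cn_delta (one row per
        locus call).
    size_changes : DataFrame, optional
        Columns line_id, subgenome, delta_mb, for the rank correlation of
        net CN change against subgenome size change.

    Returns
    -------
    dict with keys ``per_class`` (gain/loss sums per line and class),
    ``net`` (net CN change per line), ``tests`` (per-cross Wilcoxon
    signed-rank with Benjamini-Hochberg correction; all-zero crosses are
    reported as not applicable) and, when size changes are supplied,
    ``size_correlation`` (Spearman rho and p over line-subgenomes).
    """
    req = {"line_id", "cross", "sv_class", "cn_delta"}
    if not req.issubset(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(req)}")
    d = calls.copy()
    d["gain"] = d["cn_delta"].clip(lower=0)
    d["loss"] = (-d["cn_delta"]).clip(lower=0)
    per_class = (
        d.groupby(["cross", "line_id", "sv_class"])[["gain", "loss"]]
        .sum()
        .reset_index()
    )
    net = (
        d.groupby(["cross", "line_id"])["cn_delta"].sum().rename("net").reset_index()
    )
    test_rows = []
    for cross, g in net.groupby("cross"):
        vals = g["net"].to_numpy(dtype=float)
        if np.allclose(vals, 0):
            test_rows.append((cross, len(vals), float(vals.sum()), np.nan, "n/a"))
        else:
            stat, p = stats.wilcoxon(vals, alternative="two-sided")
            test_rows.append((cross, len(vals), float(vals.sum()), float(p), "ok"))
    tests = pd.DataFrame(
        test_rows, columns=["cross", "n_lines", "total_net", "p_value", "status"]
    )
    ok = tests["status"] == "ok"
    tests["p_fdr"] = np.nan
    if ok.any():
        tests.loc[ok, "p_fdr"] = multipletests(
            tests.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    tests["significant"] = tests["p_fdr"] <= alpha
    out = {"per_class": per_class, "net": net, "tests": tests}
    if size_changes is not None:
        key = ["line_id", "subgenome"]
        net_sub = (
            d.groupby(key)["cn_delta"].sum().rename("net").reset_index()
        )
        merged = net_sub.merge(size_changes, on=key, how="inner")
        if len(merged) >= 3 and merged["net"].nunique() > 1:
            rho, p = stats.spearmanr(merged["net"], merged["delta_mb"])
            out["size_correlation"] = {
                "rho": float(rho),
                "p_value": float(p),
                "n": len(merged),
            }
        else:
            out["size_correlation"] = {"rho": np.nan, "p_value": np.nan,
                                       "n": len(merged)}
    return out
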