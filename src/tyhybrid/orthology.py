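"""Projection of Ty annotations onto parental coordinates and orthologous clustering.

Evolved-line annotations are lifted over to the haploid parental coordinate
frame through per-chromosome alignment blocks, then grouped into
orthologous clusters: annotations of the same family and strand on the
same chromosome whose projected intervals chain together with gaps of at
most 500 bp form one cluster (single-linkage connected components at the
gap threshold, the 1-D equivalent of density clustering with a minimum
cluster size of one — no noise points, every annotation is assigned).
Interval gap rather than midpoint distance is used so that a 300-bp solo
LTR projected inside the span of a 6-kb parental full-length element lands
in the same cluster — an excision call depends on exactly that.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["liftover_annotations", "cluster_loci"]


def _validate_blocks(blocks: pd.DataFrame, chrom: str) -> pd.DataFrame:
    b = blocks.sort_values("src_start").reset_index(drop=True)
    ends = b["src_end"].to_numpy()
    starts = b["src_start"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError(f"overlapping contradictory liftover blocks on {chrom}")
    return b


def liftover_annotations(
    annotations: pd.DataFrame, liftover_map: dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project annotations through alignment blocks into target coordinates.

    Parameters
    ----------
    annotations : DataFrame
        BED-like table (chrom, start, end, strand, family, completeness,
        source, locus_id) in source (evolved-line) coordinates.
    liftover_map : dict of chrom -> DataFrame
        Alignment blocks with columns src_start, src_end, dst_start,
        dst_end; colinear within a block (equal lengths).

    Returns
    -------
    (projected, unmapped)
        ``projected`` carries target coordinates plus a ``projection``
        column: ``"block"`` when the annotation midpoint lies inside an
        alignment block, ``"junction"`` when it lies in a source-only
        insertion and was snapped to the flanking junction point (a zero-
        width projection — exactly what a de novo insertion produces).
        ``unmapped`` lists annotations with no usable projection; nothing
        is silently dropped.
    """
    projected_rows = []
    unmapped_rows = []
    blocks_by_chrom = {
        c: _validate_blocks(b, c) for c, b in liftover_map.items()
    }
    for _, row in annotations.iterrows():
        blocks = blocks_by_chrom.get(row.chrom)
        if blocks is None or blocks.empty:
            unmapped_rows.append(row)
            continue
        starts = blocks["src_start"].to_numpy()
        ends = blocks["src_end"].to_numpy()

        def _project(pos: int) -> int | None:
            hit = np.flatnonzero((starts <= pos) & (pos < ends))
            if not hit.size:
                return None
            b = blocks.iloc[hit[0]]
            return int(pos + (b.dst_start - b.src_start))

        # ends projected independently through their own blocks: a span
        # enclosing a source-side deletion (e.g. a truncated element)
        # projects onto the full target span
        ps = _project(row.start)
        pe = _project(row.end - 1)
        rec = row.copy()
        if ps is not None or pe is not None:
            if ps is None:
                ps = _project(row.end - 1) - (row.end - 1 - row.start)
            if pe is None:
                pe = ps + (row.end - 1 - row.start)
            rec["start"] = ps
            rec["end"] = pe + 1
            rec["projection"] = "block"
            projected_rows.append(rec)
            continue
        # whole span inside a source-only insertion: snap to the junction
        # point between the flanking blocks (a de novo insertion site)
        mid = (row.start + row.end) // 2
        before = np.flatnonzero(ends <= mid)
        if before.size:
            b = blocks.iloc[before[-1]]
            point = int(b.dst_end)
            rec["start"] = point
            rec["end"] = point
            rec["projection"] = "junction"
            projected_rows.append(rec)
        else:
            unmapped_rows.append(row)
    cols = list(annotations.columns) + ["projection"]
    projected = pd.DataFrame(projected_rows, columns=cols).reset_index(drop=True)
    unmapped = pd.DataFrame(unmapped_rows, columns=annotations.columns).reset_index(
        drop=True
    )
    return projected, unmapped


def cluster_loci(
    projected: pd.DataFrame, eps: int = 500, min_members: int = 1
) -> pd.DataFrame:
    """Assign orthologous-cluster ids to projected annotations.

    Clustering runs independently within each (chromosome, family, strand)
    partition: annotations whose projected intervals lie within ``eps``
    bases of each other (interval gap; overlapping intervals have gap 0)
    chain into one cluster. With ``min_members=1`` every annotation belongs
    to exactly one cluster. Cluster ids are canonical — ordered by
    chromosome and leftmost member — so the labelling is independent of
    input order.

    Returns the input with ``cluster_id`` and ``is_complex`` columns;
    ``is_complex`` flags clusters with more than one member from any single
    source genome.
    """
    if projected.empty:
        out = projected.copy()
        out["cluster_id"] = pd.Series(dtype=str)
        out["is_complex"] = pd.Series(dtype=bool)
        return out
    df = projected.copy().reset_index(drop=True)
    df["_key"] = -1
    key_counter = 0
    for (_chrom, _fam, _strand), g in df.groupby(
        ["chrom", "family", "strand"], sort=False
    ):
        g = g.sort_values(["start", "end"])
        max_end = None
        for idx, row in g.iterrows():
            if max_end is None or row.start - max_end > eps:
                key_counter += 1
                max_end = row.end
            else:
                max_end = max(max_end, row.end)
            df.loc[idx, "_key"] = key_counter - 1
    # canonical ids ordered by (chrom, leftmost member)
    order = (
        df.groupby("_key")
        .agg(chrom=("chrom", "first"), left=("start", "min"))
        .sort_values(["chrom", "left"])
    )
    rename = {k: f"C{i + 1:04d}" for i, k in enumerate(order.index)}
    df["cluster_id"] = df["_key"].map(rename)
    complex_ids = set()
    for cid, g in df.groupby("cluster_id"):
        if g.groupby("source").size().max() > 1:
            complex_ids.add(cid)
    df["is_complex"] = df["cluster_id"].isin(complex_ids)
    return df.drop(columns=["_key"])
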