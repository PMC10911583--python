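"""End-to-end orchestration of the synthetic hybrid Ty study.

``run_study`` wires the stages together on simulated data with recorded
ground truth: simulate a parental pair and a panel of evolved lines ->
phase reads -> call copy-number tracts and genome-size change -> project
and cluster Ty annotations -> classify each orthologous locus -> curate de
novo candidates -> tally per-line gains/losses with the per-cross tests,
and score every stage against the planted truth. ``comparison_report``
compares fluctuation-rate estimates between groups by confidence-interval
overlap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coverage, denovo, orthology, phasing, svclass
from .simulate import (
    GenomeSpec,
    HybridTruth,
    ParentalPair,
    design_study_plans,
    plant_svs,
    simulate_depth,
    simulate_parental_pair,
    simulate_reads,
)

logger = logging.getLogger("tyhybrid")

__all__ = ["StudyConfig", "StudyResult", "run_study", "comparison_report",
           "parental_tsd_table", "classify_line_subgenome"]

FLANK_EXPORT = 200  # bases of flank sequence kept per de novo candidate


@dataclass
class StudyConfig:
    """Study conditions for one synthetic cross."""

    n_chromosomes: int = 8
    chrom_length: int = 1_500_000
    snp_divergence: float = 0.01
    n_full_length: int = 30
    n_solo_ltr: int = 10
    n_lines: int = 12
    cross: str = "X1"
    # reads
    n_reads_per_line: int = 400
    mean_read_length: int = 20_000
    variant_error_rate: float = 0.0
    # depth
    mean_depth: float = 30.0
    depth_noise_frac: float = 0.0
    depth_bin: int = 10_000
    tract_window: int = 30_000
    seed: int = 0


@dataclass
class StudyResult:
    """All stage outputs plus truth-based evaluation for one synthetic cross."""

    config: StudyConfig
    pair: ParentalPair
    truths: list
    phasing_summary: pd.DataFrame
    calls: pd.DataFrame
    excluded: pd.DataFrame
    evaluation: pd.DataFrame
    curation: pd.DataFrame
    size_changes: pd.DataFrame
    tallies: dict = field(default_factory=dict)

    @property
    def class_recovery(self) -> float:
        """Fraction of evaluated loci whose predicted class matches truth."""
        if self.evaluation.empty:
            return float("nan")
        return float(self.evaluation["match"].mean())


def parental_tsd_table(pair: ParentalPair, context: int = 20) -> pd.DataFrame:
    """TSD motifs of all parental full-length copies, found from sequence."""
    rows = []
    for sub in ("P1", "P2"):
        genome = pair.genome(sub)
        ann = pair.annotations[sub]
        for _, r in ann[ann.completeness == "full-length"].iterrows():
            seq = genome.chroms[r.chrom]
            f5 = _seq_str(seq, r.start - context, r.start)
            f3 = _seq_str(seq, r.end, r.end + context)
            tsd = denovo.find_tsd(f5, f3)
            if tsd is not None:
                rows.append([sub, r.locus_id, tsd.sequence, tsd.length])
    return pd.DataFrame(rows, columns=["subgenome", "locus_id", "tsd", "tsd_len"])


def _seq_str(seq: np.ndarray, start: int, end: int) -> str:
    from .simulate import seq_to_str

    return seq_to_str(seq[max(start, 0) : end])


def classify_line_subgenome(
    pair: ParentalPair,
    truth: HybridTruth,
    sub: str,
    tracts_self: pd.DataFrame,
    tracts_homolog: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list, pd.DataFrame]:
    """Cluster, state and classify every Ty locus of one line subgenome.

    Returns (calls, excluded, denovo_candidates, clustered annotations);
    candidate dicts carry the flank sequences needed by the curation stage.
    """
    line_ann = truth.annotations[sub].copy()
    line_ann["orig_start"] = line_ann["start"]
    line_ann["orig_end"] = line_ann["end"]
    projected, unmapped = orthology.liftover_annotations(
        line_ann, truth.liftover[sub]
    )
    parent_ann = pair.annotations[sub].copy()
    parent_ann["source"] = "parent"
    parent_ann["projection"] = "block"
    parent_ann["orig_start"] = parent_ann["start"]
    parent_ann["orig_end"] = parent_ann["end"]
    combined = pd.concat([parent_ann, projected], ignore_index=True)
    clustered = orthology.cluster_loci(combined)

    chrom_lengths = pair.genome(sub).lengths()
    reverse_map = truth.reverse_liftover(sub)
    calls, excluded, candidates = [], [], []
    for cid, g in clustered.groupby("cluster_id"):
        par = g[g.source == "parent"]
        ma = g[g.source != "parent"]
        chrom = g.chrom.iloc[0]
        if len(par):
            span = (int(par.start.min()), int(par.end.max()))
        else:
            span = (int(ma.start.min()), int(ma.end.max()))
        state = svclass.LocusState(
            cluster_id=cid,
            line_id=truth.line_id,
            subgenome=sub,
            chrom=chrom,
            span=span,
            is_complex=bool(g.is_complex.iloc[0]),
            parent_types=tuple(
                sorted(zip(par.family, par.completeness))
            ),
            ma_types=tuple(sorted(zip(ma.family, ma.completeness))),
            cn_ma=coverage.locus_cn(tracts_self, chrom, *span),
            cn_parent=float(truth.plan.baseline_copies.get(sub, 1)),
            assembly_present=svclass.assembly_presence(
                span, chrom, chrom_lengths[chrom], reverse_map
            ),
        )
        if svclass.consistency_filter(state.cn_ma, state.assembly_present) == "exclude":
            excluded.append(
                [truth.line_id, sub, cid, state.cn_ma, state.assembly_present]
            )
            continue
        call = svclass.classify_locus(state)
        if call.sv_class == "cn_change":
            call = svclass.subclassify_cn_change(
                call,
                span,
                chrom,
                tracts_self,
                tracts_homolog,
                chrom_lengths[chrom],
                ploidy=truth.ploidy[sub],
            )
        calls.append(
            [truth.line_id, sub, cid, chrom, span[0], span[1],
             call.sv_class, call.cn_delta]
        )
        if call.sv_class == "denovo_candidate":
            candidates.append(
                _denovo_candidate(truth, sub, cid, ma)
            )
    calls_df = pd.DataFrame(
        calls,
        columns=["line_id", "subgenome", "cluster_id", "chrom", "start", "end",
                 "sv_class", "cn_delta"],
    )
    excluded_df = pd.DataFrame(
        excluded,
        columns=["line_id", "subgenome", "cluster_id", "cn_ma", "present"],
    )
    return calls_df, excluded_df, candidates, clustered


def _denovo_candidate(truth: HybridTruth, sub: str, cid: str, ma: pd.DataFrame):
    """Extract flank sequences for the additional full-length annotation."""
    fulls = ma[ma.completeness == "full-length"]
    junction = fulls[fulls.projection == "junction"]
    pick = junction.iloc[0] if len(junction) else fulls.iloc[0]
    seq = truth.sequences[sub][pick.chrom]
    ls, le = int(pick.orig_start), int(pick.orig_end)
    return dict(
        locus_id=f"{truth.line_id}:{sub}:{cid}",
        line_id=truth.line_id,
        subgenome=sub,
        cluster_id=cid,
        family=pick.family,
        flank5=_seq_str(seq, ls - FLANK_EXPORT, ls),
        flank3=_seq_str(seq, le, le + FLANK_EXPORT),
    )


def _expected_class(
    truth: HybridTruth, sub: str, cluster_row: pd.Series, member_loci: set
) -> str:
    tc = truth.true_classes
    sel = tc[(tc.subgenome == sub) & (tc.locus_id.isin(member_loci))]
    non_trivial = sorted(set(sel.sv_class) - {"no_change"})
    if len(non_trivial) > 1:
        # conflicting planted classes on one cluster (excluded by plan
        # validation; defensive)
        return "conflict"
    return non_trivial[0] if non_trivial else "no_change"


_PREDICTED_TO_TRUTH = {"denovo_candidate": "denovo"}


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full synthetic study and score it against the planted truth."""
    t0 = time.time()
    spec = GenomeSpec(
        n_chromosomes=config.n_chromosomes,
        chrom_length=config.chrom_length,
        snp_divergence=config.snp_divergence,
        n_full_length={"Ty1": config.n_full_length},
        n_solo_ltr={"Ty1": config.n_solo_ltr},
        seed=config.seed,
    )
    pair = simulate_parental_pair(spec)
    plans = design_study_plans(pair, config.n_lines, seed=config.seed + 1)
    logger.info(
        "simulate: %d chromosomes x %d bp, %d Ty loci, %d lines (%.1fs)",
        config.n_chromosomes, config.chrom_length,
        len(pair.elements), config.n_lines, time.time() - t0,
    )

    phasing_rows = []
    all_calls, all_excl, all_eval, all_sizes = [], [], [], []
    candidates = []
    truths = []
    for i, plan in enumerate(plans):
        truth = plant_svs(pair, plan, seed=config.seed + 10 + i)
        truths.append(truth)
        # --- phase
        reads = simulate_reads(
            truth,
            config.n_reads_per_line,
            mean_length=config.mean_read_length,
            variant_error_rate=config.variant_error_rate,
            seed=config.seed + 100 + i,
        )
        result = phasing.phase_library(reads, pair.variants)
        classified = result.reads[result.reads.call != "unclassified"]
        mis = int((classified.call != classified.true_origin).sum())
        phasing_rows.append(
            [plan.line_id, len(reads), len(classified), mis,
             result.classification_rate]
        )
        # --- depth, tracts, size change
        depth = simulate_depth(
            truth,
            mean_depth=config.mean_depth,
            noise_sd=config.depth_noise_frac * config.mean_depth,
            window=config.depth_bin,
            seed=config.seed + 200 + i,
        )
        tracts = {
            sub: coverage.depth_to_tracts(
                depth[sub],
                window=config.tract_window,
                baseline_copies=truth.ploidy[sub],
            )
            for sub in ("P1", "P2")
        }
        for sub in ("P1", "P2"):
            sc = coverage.genome_size_change(depth[sub], bin_size=config.depth_bin)
            all_sizes.append([plan.line_id, sub, sc.delta_mb, sc.bins_used,
                              sc.excluded_bins])
        # --- cluster + classify per subgenome
        for sub in ("P1", "P2"):
            calls_df, excl_df, cands, clustered = classify_line_subgenome(
                pair, truth, sub, tracts[sub], tracts["P2" if sub == "P1" else "P1"]
            )
            candidates.extend(cands)
            all_calls.append(calls_df)
            all_excl.append(excl_df)
            # --- evaluation against truth
            parent_members = {
                cid: set(g.loc[g.source == "parent", "locus_id"])
                for cid, g in clustered.groupby("cluster_id")
            }
            dn = truth.denovo_records
            for _, c in calls_df.iterrows():
                members = set(parent_members.get(c.cluster_id, set()))
                if len(dn):
                    hit = dn[
                        (dn.subgenome == sub)
                        & (dn.chrom == c.chrom)
                        & (dn.parent_pos >= c.start - 500)
                        & (dn.parent_pos <= c.end + 500)
                    ]
                    members |= set(hit.locus_id)
                expected = _expected_class(truth, sub, c, members)
                predicted = _PREDICTED_TO_TRUTH.get(c.sv_class, c.sv_class)
                all_eval.append(
                    [plan.line_id, sub, c.cluster_id, expected, predicted,
                     expected == predicted]
                )
        logger.info("line %s done (%.1fs)", plan.line_id, time.time() - t0)

    curation = denovo.curate_candidates(
        candidates,
        {"P1": pair.p1, "P2": pair.p2},
        parental_tsd_table(pair).tsd.tolist(),
    )
    calls = pd.concat(all_calls, ignore_index=True)
    calls["cross"] = config.cross
    non_empty_excl = [d for d in all_excl if len(d)]
    excluded = (
        pd.concat(non_empty_excl, ignore_index=True)
        if non_empty_excl
        else all_excl[0]
    )
    size_changes = pd.DataFrame(
        all_sizes,
        columns=["line_id", "subgenome", "delta_mb", "bins_used", "excluded_bins"],
    )
    tallies = svclass.tally_and_test(
        calls, size_changes[["line_id", "subgenome", "delta_mb"]]
    )
    evaluation = pd.DataFrame(
        all_eval,
        columns=["line_id", "subgenome", "cluster_id", "expected", "predicted",
                 "match"],
    )
    phasing_summary = pd.DataFrame(
        phasing_rows,
        columns=["line_id", "n_reads", "n_classified", "n_misclassified",
                 "pct_bases_classified"],
    )
    logger.info("study complete (%.1fs)", time.time() - t0)
    return StudyResult(
        config=config,
        pair=pair,
        truths=truths,
        phasing_summary=phasing_summary,
        calls=calls,
        excluded=excluded,
        evaluation=evaluation,
        curation=curation,
        size_changes=size_changes,
        tallies=tallies,
    )


def comparison_report(estimates: pd.DataFrame, group_col: str = "label") -> pd.DataFrame:
    """Pairwise rate ratios with a CI-overlap significance call.

    ``estimates`` needs columns ``rate``, ``ci_low``, ``ci_high`` (rate
    units), ``is_upper_bound`` and the grouping column. Two estimates are
    called significantly different when their confidence intervals do not
    overlap; ratios involving an upper-bound estimate are flagged as bounds.
    """
    req = {group_col, "rate", "ci_low", "ci_high", "is_upper_bound"}
    if not req.issubset(estimates.columns):
        raise ValueError(f"estimates table needs columns {sorted(req)}")
    if estimates[group_col].nunique() < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    groups = list(estimates[group_col])
    for i in range(len(estimates)):
        for j in range(i + 1, len(estimates)):
            a, b = estimates.iloc[i], estimates.iloc[j]
            ratio = a.rate / b.rate if b.rate > 0 else np.inf
            overlap = (a.ci_low <= b.ci_high) and (b.ci_low <= a.ci_high)
            rows.append(
                [
                    groups[i],
                    groups[j],
                    ratio,
                    not overlap,
                    bool(a.is_upper_bound or b.is_upper_bound),
                ]
            )
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "rate_ratio", "significant", "is_bound"],
    )
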