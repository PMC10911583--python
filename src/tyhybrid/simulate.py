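"""Synthetic hybrid yeast genomes with planted Ty structural variants.

Everything downstream (phasing, copy-number tracts, orthology, SV calls,
TSD curation, fluctuation rates) is exercised against data produced here,
with full ground truth recorded: two diverged parental genomes carrying
full-length Ty elements (two identical LTRs flanking an internal region)
and solo LTRs, evolved hybrid subgenomes with planted SV events of every
class (polyploidy, aneuploidy, LOH, truncation, excision, deletion, de novo
insertion), read-level variant observations, per-window depth tracks and
Luria-Delbruck fluctuation cultures.

Sequences are random DNA; Ty family identity is metadata. Every planted
element is flanked by an exact 5-6 nt target-site duplication, as left by
the staggered cut of a retroviral-like integrase. Parental divergence is
uniform substitution outside element/TSD spans, so parental element copies
stay internally exact (mirroring the repeat-masked variant sets a real
analysis would use).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TyFamily",
    "GenomeSpec",
    "Genome",
    "ParentalPair",
    "SVEvent",
    "SVPlan",
    "HybridTruth",
    "ReadObservation",
    "simulate_parental_pair",
    "plant_svs",
    "simulate_reads",
    "simulate_depth",
    "simulate_fluctuation_cultures",
    "design_study_plans",
    "make_curation_fixture",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SV_CLASSES = (
    "no_change",
    "polyploidy",
    "aneuploidy",
    "loh",
    "truncation",
    "excision",
    "denovo",
    "deletion",
)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def seq_to_str(seq: np.ndarray) -> str:
    return BASES[seq].tobytes().decode("ascii")


def str_to_seq(s: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
    if np.any(arr == 255):
        raise ValueError("non-ACGT symbol in sequence")
    return arr


def revcomp(seq: np.ndarray) -> np.ndarray:
    return (3 - seq)[::-1]


@dataclass(frozen=True)
class TyFamily:
    """One Ty retrotransposon family: full-length and LTR sizes in bases."""

    name: str
    full_length: int = 5900
    ltr: int = 330

    @property
    def internal(self) -> int:
        return self.full_length - 2 * self.ltr


@dataclass
class GenomeSpec:
    """Parameters of one simulated parental genome pair."""

    n_chromosomes: int = 8
    chrom_length: int = 1_500_000
    snp_divergence: float = 0.01
    te_families: tuple[TyFamily, ...] = (TyFamily("Ty1"),)
    n_full_length: dict = field(default_factory=lambda: {"Ty1": 30})
    n_solo_ltr: dict = field(default_factory=lambda: {"Ty1": 10})
    tsd_lengths: tuple[int, ...] = (5, 6)
    min_spacing: int = 3000
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.snp_divergence < 0.25):
            raise ValueError("snp_divergence must be in [0, 0.25)")
        for fam in self.te_families:
            if self.chrom_length <= 10 * fam.full_length:
                raise ValueError(
                    f"chrom_length must exceed 10x full-length size of {fam.name}"
                )
        for k in self.tsd_lengths:
            if k not in (5, 6):
                raise ValueError("TSD lengths must be 5 or 6")


@dataclass
class Genome:
    """A named set of chromosome sequences (uint8-coded ACGT)."""

    name: str
    chroms: dict

    def lengths(self) -> dict:
        return {c: len(s) for c, s in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.chroms[chrom][max(start, 0) : end]


_ANN_COLS = [
    "chrom",
    "start",
    "end",
    "strand",
    "family",
    "completeness",
    "source",
    "locus_id",
]


@dataclass
class ParentalPair:
    """Two diverged parents with shared Ty landscape and informative variants."""

    p1: Genome
    p2: Genome
    annotations: dict  # {"P1": DataFrame, "P2": DataFrame} in _ANN_COLS
    variants: pd.DataFrame  # var_id, chrom, pos, P1, P2 (allele letters)
    elements: pd.DataFrame  # per-locus truth incl. TSD sequence
    spec: GenomeSpec

    def genome(self, subgenome: str) -> Genome:
        return self.p1 if subgenome == "P1" else self.p2


def _place_elements(
    rng: np.random.Generator, spec: GenomeSpec
) -> list[dict]:
    """Choose non-overlapping background insertion points for all elements."""
    chrom_names = [f"chr{i + 1:02d}" for i in range(spec.n_chromosomes)]
    placements: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    fam_by_name = {f.name: f for f in spec.te_families}
    jobs = []
    for fam in spec.te_families:
        jobs += [(fam.name, "full-length")] * spec.n_full_length.get(fam.name, 0)
        jobs += [(fam.name, "solo-LTR")] * spec.n_solo_ltr.get(fam.name, 0)
    margin = min(50_000, spec.chrom_length // 10)
    for idx, (fam_name, completeness) in enumerate(jobs):
        fam = fam_by_name[fam_name]
        size = fam.full_length if completeness == "full-length" else fam.ltr
        chrom = chrom_names[idx % len(chrom_names)]
        placed = False
        for _ in range(1000):
            pos = int(rng.integers(margin, spec.chrom_length - margin - size))
            span = (pos - spec.min_spacing, pos + size + spec.min_spacing)
            if all(e <= span[0] or s >= span[1] for s, e in occupied[chrom]):
                occupied[chrom].append(span)
                placements.append(
                    dict(
                        chrom=chrom,
                        pos=pos,
                        family=fam_name,
                        completeness=completeness,
                        strand=str(rng.choice(["+", "-"])),
                        tsd_len=int(rng.choice(spec.tsd_lengths)),
                        ltr=fam.ltr,
                        size=size,
                    )
                )
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place element {idx} ({fam_name}) on {chrom}: "
                "chromosome too full"
            )
    return placements


def simulate_parental_pair(spec: GenomeSpec) -> ParentalPair:
    """Generate two parental genomes, Ty annotations and informative variants.

    Both parents carry the same element placements at identical coordinates
    (substitutions are length-neutral), so parental coordinates form a
    shared reference frame for the whole cross. Deterministic per
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    placements = _place_elements(rng, spec)

    chrom_names = [f"chr{i + 1:02d}" for i in range(spec.n_chromosomes)]
    p1_chroms: dict[str, np.ndarray] = {}
    ann_rows = []
    elem_rows = []
    mask_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    locus_counter = 0
    for chrom in chrom_names:
        bg = _random_seq(rng, spec.chrom_length)
        ins = sorted(
            (p for p in placements if p["chrom"] == chrom),
            key=lambda p: p["pos"],
        )
        pieces = []
        cursor = 0
        offset = 0
        for p in ins:
            pos, k = p["pos"], p["tsd_len"]
            ltr = _random_seq(rng, p["ltr"])
            if p["completeness"] == "full-length":
                internal = _random_seq(rng, p["size"] - 2 * p["ltr"])
                element = np.concatenate([ltr, internal, ltr])
            else:
                element = ltr
            if p["strand"] == "-":
                element = revcomp(element)
            # duplicate the k-base target site: bg[:pos+k] + element + bg[pos:]
            pieces.append(bg[cursor : pos + k])
            pieces.append(element)
            cursor = pos
            start = pos + k + offset  # element start in final coords
            end = start + len(element)
            offset += k + len(element)
            locus_counter += 1
            locus_id = f"L{locus_counter:03d}"
            tsd = seq_to_str(bg[pos : pos + k])
            ann_rows.append(
                [chrom, start, end, p["strand"], p["family"],
                 p["completeness"], "parent", locus_id]
            )
            elem_rows.append(
                dict(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=p["strand"],
                    family=p["family"],
                    completeness=p["completeness"],
                    tsd=tsd,
                    tsd_len=k,
                    ltr_len=p["ltr"],
                )
            )
            mask_spans[chrom].append((start - k, end + k))
        pieces.append(bg[cursor:])
        p1_chroms[chrom] = np.concatenate(pieces)

    ann = pd.DataFrame(ann_rows, columns=_ANN_COLS)

    # P2 = P1 with substitutions outside element/TSD spans
    p2_chroms = {}
    var_rows = []
    var_counter = 0
    for chrom in chrom_names:
        seq = p1_chroms[chrom].copy()
        editable = np.ones(len(seq), dtype=bool)
        for s, e in mask_spans[chrom]:
            editable[max(s, 0) : e] = False
        hit = (rng.random(len(seq)) < spec.snp_divergence) & editable
        sites = np.flatnonzero(hit)
        if sites.size:
            shift = rng.integers(1, 4, size=sites.size, dtype=np.uint8)
            seq[sites] = (seq[sites] + shift) % 4
        p2_chroms[chrom] = seq
        for pos in sites:
            var_rows.append(
                [
                    f"v{var_counter:06d}",
                    chrom,
                    int(pos),
                    seq_to_str(p1_chroms[chrom][pos : pos + 1]),
                    seq_to_str(seq[pos : pos + 1]),
                ]
            )
            var_counter += 1
    variants = pd.DataFrame(
        var_rows, columns=["var_id", "chrom", "pos", "P1", "P2"]
    )

    ann_p1 = ann.assign(source="P1")
    ann_p2 = ann.assign(source="P2")
    return ParentalPair(
        p1=Genome("P1", p1_chroms),
        p2=Genome("P2", p2_chroms),
        annotations={"P1": ann_p1, "P2": ann_p2},
        variants=variants,
        elements=pd.DataFrame(elem_rows),
        spec=spec,
    )


# --------------------------------------------------------------------------
# SV planting
# --------------------------------------------------------------------------


@dataclass
class SVEvent:
    """One planted structural-variant event.

    ``kind`` is one of polyploidy, aneuploidy, loh, truncation, excision,
    deletion, denovo. ``subgenome`` names the affected haplotype; locus-level
    kinds target ``locus_id``; loh uses ``chrom``/``start``/``end`` (tract in
    parental coordinates, lost from ``subgenome`` and duplicated in the
    homolog); aneuploidy uses ``chrom`` and ``copies`` (0 = loss, 2 = gain);
    polyploidy sets the whole-subgenome copy count to ``copies``.
    """

    kind: str
    subgenome: str = "P1"
    chrom: str | None = None
    locus_id: str | None = None
    start: int | None = None
    end: int | None = None
    copies: int = 2
    position: int | None = None  # de novo insertion point (parent coords)
    tsd_length: int = 5
    family: str = "Ty1"
    nested: bool = False
    truncation_fraction: float = 0.5


@dataclass
class SVPlan:
    """The set of SV events applied to one evolved line."""

    events: list = field(default_factory=list)
    baseline_copies: dict = field(
        default_factory=lambda: {"P1": 1, "P2": 1}
    )
    line_id: str = "line"


@dataclass
class ReadObservation:
    """Variant support observed on one simulated read."""

    read_id: str
    true_origin: str
    length: int
    observed_alleles: list  # [(var_id, allele in {"P1","P2","error"})]


@dataclass
class HybridTruth:
    """Evolved line with complete ground truth for every downstream stage."""

    line_id: str
    pair: ParentalPair
    plan: SVPlan
    sequences: dict  # {sub: {chrom: np.ndarray}} (phased assembly analogue)
    annotations: dict  # {sub: DataFrame} in line coordinates
    liftover: dict  # {sub: {chrom: blocks df src_*=line dst_*=parent}}
    ploidy: dict  # {sub: int} whole-subgenome copy count
    cn_profiles: dict  # {sub: {chrom: [(start,end,copies)]}}
    true_classes: pd.DataFrame  # locus_id, subgenome, sv_class
    denovo_records: pd.DataFrame

    def copies_at(self, subgenome: str, chrom: str, pos: int) -> int:
        for s, e, c in self.cn_profiles[subgenome][chrom]:
            if s <= pos < e:
                return c
        raise KeyError(f"{chrom}:{pos} outside profile")

    def reverse_liftover(self, subgenome: str) -> dict:
        """Parent -> line alignment blocks (for assembly-presence checks)."""
        out = {}
        for chrom, blocks in self.liftover[subgenome].items():
            out[chrom] = blocks.rename(
                columns={
                    "src_start": "dst_start",
                    "src_end": "dst_end",
                    "dst_start": "src_start",
                    "dst_end": "src_end",
                }
            )[["src_start", "src_end", "dst_start", "dst_end"]]
        return out


def _validate_plan(pair: ParentalPair, plan: SVPlan) -> None:
    elements = pair.elements.set_index("locus_id")
    lengths = pair.p1.lengths()
    targeted: dict[tuple, str] = {}
    loh_tracts: list[tuple[str, str, int, int]] = []
    for ev in plan.events:
        if ev.kind not in SV_CLASSES or ev.kind == "no_change":
            raise ValueError(f"unknown SV kind {ev.kind!r}")
        if ev.subgenome not in ("P1", "P2"):
            raise ValueError(f"unknown subgenome {ev.subgenome!r}")
        if ev.kind in ("truncation", "excision", "deletion"):
            if ev.locus_id not in elements.index:
                raise ValueError(f"{ev.kind} targets unknown locus {ev.locus_id}")
            key = (ev.subgenome, ev.locus_id)
            if key in targeted:
                raise ValueError(
                    f"conflicting events on locus {ev.locus_id} "
                    f"({targeted[key]} vs {ev.kind})"
                )
            targeted[key] = ev.kind
        if ev.kind == "loh":
            L = lengths[ev.chrom]
            if not (0 <= ev.start < ev.end <= L):
                raise ValueError(f"LOH tract out of bounds on {ev.chrom}")
            loh_tracts.append((ev.subgenome, ev.chrom, ev.start, ev.end))
        if ev.kind == "denovo" and ev.tsd_length not in (5, 6):
            raise ValueError("TSD length must be 5 or 6")
    for (sub, locus), kind in targeted.items():
        row = elements.loc[locus]
        for lsub, lchrom, ls, le in loh_tracts:
            if lsub == sub and lchrom == row.chrom and ls < row.end and le > row.start:
                raise ValueError(
                    f"conflicting events: {kind} on {locus} lies inside an "
                    f"LOH tract on {sub} {lchrom}"
                )


def _other(sub: str) -> str:
    return "P2" if sub == "P1" else "P1"


def plant_svs(
    pair: ParentalPair, plan: SVPlan, seed: int = 0
) -> HybridTruth:
    """Apply an SV plan to the parental pair, returning the evolved line.

    Sequence-level semantics per class: excision keeps the first LTR of a
    full-length element and removes the rest (intra-element LTR-LTR
    recombination); truncation removes an internal fraction; deletion removes
    the element together with one TSD copy, restoring the pre-insertion
    site; de novo copies an existing parental donor element into a fresh
    site with a new 5-6 nt TSD; LOH removes the tract from the losing
    subgenome's phased representation (its reads would sort to the homolog)
    and doubles the homolog's copy number over the tract.
    """
    _validate_plan(pair, plan)
    rng = np.random.default_rng(seed)
    elements = pair.elements.set_index("locus_id")

    ploidy = dict(plan.baseline_copies)
    chrom_copies: dict[tuple, int] = {}
    # edits[sub][chrom] = list of (start, end, replacement, tag)
    edits: dict[str, dict[str, list]] = {"P1": {}, "P2": {}}
    drop_loci: dict[str, set] = {"P1": set(), "P2": set()}
    truncate_loci: dict[str, dict] = {"P1": {}, "P2": {}}
    solo_loci: dict[str, dict] = {"P1": {}, "P2": {}}
    denovo_rows: list[dict] = []
    loh_tracts: list[tuple[str, str, int, int]] = []
    dropped_chroms: dict[str, set] = {"P1": set(), "P2": set()}

    class_rows = []

    def set_class(locus_id: str, sub: str, sv_class: str) -> None:
        class_rows.append((locus_id, sub, sv_class))

    dn_counter = 0
    for ev in plan.events:
        sub = ev.subgenome
        genome = pair.genome(sub)
        if ev.kind == "polyploidy":
            ploidy[sub] = ev.copies
            for locus_id, row in elements.iterrows():
                set_class(locus_id, sub, "polyploidy")
        elif ev.kind == "aneuploidy":
            chrom_copies[(sub, ev.chrom)] = ev.copies
            if ev.copies == 0:
                dropped_chroms[sub].add(ev.chrom)
            for locus_id, row in elements.iterrows():
                if row.chrom == ev.chrom:
                    set_class(locus_id, sub, "aneuploidy")
        elif ev.kind == "loh":
            edits[sub].setdefault(ev.chrom, []).append(
                (ev.start, ev.end, np.empty(0, dtype=np.uint8), "loh")
            )
            loh_tracts.append((sub, ev.chrom, ev.start, ev.end))
            for locus_id, row in elements.iterrows():
                if row.chrom == ev.chrom and ev.start < row.end and ev.end > row.start:
                    set_class(locus_id, sub, "loh")
                    set_class(locus_id, _other(sub), "loh")
        elif ev.kind == "truncation":
            row = elements.loc[ev.locus_id]
            if row.completeness != "full-length":
                raise ValueError(f"truncation target {ev.locus_id} not full-length")
            internal = row.end - row.start - 2 * row.ltr_len
            cut = max(int(ev.truncation_fraction * internal), 1)
            cut_start = row.start + row.ltr_len + (internal - cut) // 2
            edits[sub].setdefault(row.chrom, []).append(
                (cut_start, cut_start + cut, np.empty(0, dtype=np.uint8), "trunc")
            )
            truncate_loci[sub][ev.locus_id] = cut
            set_class(ev.locus_id, sub, "truncation")
        elif ev.kind == "excision":
            row = elements.loc[ev.locus_id]
            if row.completeness != "full-length":
                raise ValueError(f"excision target {ev.locus_id} not full-length")
            edits[sub].setdefault(row.chrom, []).append(
                (row.start + row.ltr_len, row.end, np.empty(0, dtype=np.uint8), "exc")
            )
            solo_loci[sub][ev.locus_id] = row.ltr_len
            set_class(ev.locus_id, sub, "excision")
        elif ev.kind == "deletion":
            row = elements.loc[ev.locus_id]
            edits[sub].setdefault(row.chrom, []).append(
                (row.start, row.end + row.tsd_len, np.empty(0, dtype=np.uint8), "del")
            )
            drop_loci[sub].add(ev.locus_id)
            set_class(ev.locus_id, sub, "deletion")
        elif ev.kind == "denovo":
            donors = elements[
                (elements.family == ev.family)
                & (elements.completeness == "full-length")
            ]
            if donors.empty:
                raise ValueError(f"no full-length {ev.family} donor in parents")
            donor = donors.iloc[int(rng.integers(len(donors)))]
            elem_seq = genome.chroms[donor.chrom][donor.start : donor.end].copy()
            k = ev.tsd_length
            parental_tsds = set(elements.tsd)
            if ev.position is not None:
                chrom, p = ev.chrom, ev.position
            else:
                # resample until the target site yields a TSD motif distinct
                # from every parental one, so the planted insertion is
                # curatable as genuine
                for _ in range(100):
                    chrom, p = _pick_insertion_site(rng, pair, ev, elements)
                    if seq_to_str(genome.chroms[chrom][p : p + k]) not in parental_tsds:
                        break
            tsd_seq = genome.chroms[chrom][p : p + k].copy()
            replacement = np.concatenate([elem_seq, tsd_seq])
            edits[sub].setdefault(chrom, []).append(
                (p + k, p + k, replacement, "denovo")
            )
            dn_counter += 1
            locus_id = f"{plan.line_id}.DN{dn_counter:02d}"
            denovo_rows.append(
                dict(
                    locus_id=locus_id,
                    subgenome=sub,
                    chrom=chrom,
                    parent_pos=p,
                    elem_len=len(elem_seq),
                    tsd=seq_to_str(tsd_seq),
                    tsd_len=k,
                    family=ev.family,
                    strand=donor.strand,
                    nested=ev.nested,
                )
            )
            set_class(locus_id, sub, "denovo")

    sequences: dict[str, dict] = {}
    annotations: dict[str, pd.DataFrame] = {}
    liftover: dict[str, dict] = {}
    for sub in ("P1", "P2"):
        genome = pair.genome(sub)
        seqs, anns, blocks = _apply_edits(
            genome,
            pair.annotations[sub],
            edits[sub],
            drop_loci[sub],
            truncate_loci[sub],
            solo_loci[sub],
            dropped_chroms[sub],
            [r for r in denovo_rows if r["subgenome"] == sub],
            loh_tracts,
            sub,
            plan.line_id,
        )
        sequences[sub] = seqs
        annotations[sub] = anns
        liftover[sub] = blocks

    # per-chromosome copy-number profiles in parental coordinates
    cn_profiles: dict[str, dict] = {"P1": {}, "P2": {}}
    for sub in ("P1", "P2"):
        for chrom, L in pair.genome(sub).lengths().items():
            base = chrom_copies.get((sub, chrom), ploidy[sub])
            segs = [(0, L, base)]
            for lsub, lchrom, ls, le in loh_tracts:
                if lchrom != chrom:
                    continue
                new_copies = (
                    0
                    if lsub == sub
                    else ploidy[sub] + plan.baseline_copies.get(lsub, 1)
                )
                segs = _override_segment(segs, ls, le, new_copies)
            cn_profiles[sub][chrom] = segs

    base_rows = [
        (locus_id, sub, "no_change")
        for locus_id in elements.index
        for sub in ("P1", "P2")
    ]
    truth_classes = pd.DataFrame(
        base_rows + class_rows, columns=["locus_id", "subgenome", "sv_class"]
    ).drop_duplicates(subset=["locus_id", "subgenome"], keep="last")

    return HybridTruth(
        line_id=plan.line_id,
        pair=pair,
        plan=plan,
        sequences=sequences,
        annotations=annotations,
        liftover=liftover,
        ploidy=ploidy,
        cn_profiles=cn_profiles,
        true_classes=truth_classes.reset_index(drop=True),
        denovo_records=pd.DataFrame(denovo_rows),
    )


def _pick_insertion_site(rng, pair, ev, elements):
    """Choose a de novo target site away from (or nested in) existing loci."""
    lengths = pair.p1.lengths()
    chrom_names = list(lengths)
    if ev.nested:
        fulls = elements[elements.completeness == "full-length"]
        host = fulls.iloc[int(rng.integers(len(fulls)))]
        # inside the host's left LTR
        return host.chrom, int(host.start + host.ltr_len // 2)
    for _ in range(1000):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        p = int(rng.integers(20_000, lengths[chrom] - 20_000))
        near = elements[
            (elements.chrom == chrom)
            & (elements.start - 2000 < p)
            & (elements.end + 2000 > p)
        ]
        if near.empty:
            return chrom, p
    raise RuntimeError("could not find an insertion site")


def _override_segment(segs, start, end, copies):
    out = []
    for s, e, c in segs:
        if e <= start or s >= end:
            out.append((s, e, c))
            continue
        if s < start:
            out.append((s, start, c))
        out.append((max(s, start), min(e, end), copies))
        if e > end:
            out.append((end, e, c))
    return out


def _apply_edits(
    genome,
    parent_ann,
    chrom_edits,
    drop_loci,
    truncate_loci,
    solo_loci,
    dropped_chroms,
    denovo_rows,
    loh_tracts,
    sub,
    line_id,
):
    """Apply sequence edits; return line sequences, annotations and liftover."""
    sequences = {}
    blocks_by_chrom = {}
    ann_rows = []

    # annotations lost to LOH tracts on this subgenome
    loh_lost = set()
    for lsub, lchrom, ls, le in loh_tracts:
        if lsub != sub:
            continue
        hit = parent_ann[
            (parent_ann.chrom == lchrom)
            & (parent_ann.start < le)
            & (parent_ann.end > ls)
        ]
        loh_lost.update(hit.locus_id)

    for chrom, seq in genome.chroms.items():
        if chrom in dropped_chroms:
            continue
        edits = sorted(chrom_edits.get(chrom, []), key=lambda e: e[0])
        for (s1, e1, *_), (s2, e2, *_) in zip(edits, edits[1:]):
            if e1 > s2:
                raise ValueError(f"conflicting overlapping edits on {chrom}")
        pieces = []
        blocks = []
        cursor = 0
        line_pos = 0
        shifts = []  # (parent_end_of_edit, cumulative_shift)
        shift = 0
        insert_pos = {}  # parent point -> line start of replacement
        for s, e, repl, tag in edits:
            if s > cursor:
                pieces.append(seq[cursor:s])
                blocks.append((line_pos, line_pos + s - cursor, cursor, s))
                line_pos += s - cursor
            if len(repl):
                insert_pos[(s, tag)] = line_pos
                pieces.append(repl)
                line_pos += len(repl)
            shift += len(repl) - (e - s)
            shifts.append((e, shift))
            cursor = e
        if cursor < len(seq):
            pieces.append(seq[cursor:])
            blocks.append((line_pos, line_pos + len(seq) - cursor, cursor, len(seq)))
        sequences[chrom] = (
            np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
        )
        blocks_by_chrom[chrom] = pd.DataFrame(
            blocks, columns=["src_start", "src_end", "dst_start", "dst_end"]
        )

        def to_line(x: int) -> int:
            off = 0
            for pe, sh in shifts:
                if pe <= x:
                    off = sh
                else:
                    break
            return x + off

        sub_ann = parent_ann[parent_ann.chrom == chrom]
        for _, row in sub_ann.iterrows():
            if row.locus_id in drop_loci or row.locus_id in loh_lost:
                continue
            completeness = row.completeness
            end_parent = row.end
            if row.locus_id in solo_loci:
                completeness = "solo-LTR"
            elif row.locus_id in truncate_loci:
                completeness = "truncated"
            ann_rows.append(
                [
                    chrom,
                    to_line(row.start),
                    to_line(end_parent),
                    row.strand,
                    row.family,
                    completeness,
                    f"{line_id}:{sub}",
                    row.locus_id,
                ]
            )
        for rec in denovo_rows:
            if rec["chrom"] != chrom:
                continue
            start = insert_pos[(rec["parent_pos"] + rec["tsd_len"], "denovo")]
            ann_rows.append(
                [
                    chrom,
                    start,
                    start + rec["elem_len"],
                    rec["strand"],
                    rec["family"],
                    "full-length",
                    f"{line_id}:{sub}",
                    rec["locus_id"],
                ]
            )

    anns = pd.DataFrame(ann_rows, columns=_ANN_COLS)
    return sequences, anns, blocks_by_chrom


# --------------------------------------------------------------------------
# Reads, depth, fluctuation cultures
# --------------------------------------------------------------------------


def simulate_reads(
    truth: HybridTruth,
    n_reads: int,
    mean_length: float = 20_000,
    variant_error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadObservation]:
    """Draw reads from the evolved line and report their variant support.

    Reads are positioned on the shared parental coordinate frame; each read
    lists the informative variants it covers with the allele of its true
    subgenome of origin, flipped to the wrong parent with probability
    ``variant_error_rate``. Subgenomes and chromosomes are sampled
    proportional to their copy number, so ploidy shifts show up in base
    ratios. Lengths are lognormal around ``mean_length`` (long-read-like
    spread).
    """
    if not (0 <= variant_error_rate < 0.5):
        raise ValueError("variant_error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    variants = truth.pair.variants
    var_by_chrom = {
        c: g.sort_values("pos").reset_index(drop=True)
        for c, g in variants.groupby("chrom")
    }
    lengths = truth.pair.p1.lengths()
    units = []  # (sub, chrom, weight)
    for sub in ("P1", "P2"):
        for chrom, L in lengths.items():
            copies = truth.chrom_mean_copies(sub, chrom)
            if copies > 0:
                units.append((sub, chrom, copies * L))
    w = np.array([u[2] for u in units], dtype=float)
    w /= w.sum()
    choice = rng.choice(len(units), size=n_reads, p=w)
    sigma = 0.6
    mu_ln = math.log(mean_length) - sigma**2 / 2
    read_lengths = np.maximum(
        rng.lognormal(mu_ln, sigma, size=n_reads).astype(int), 200
    )
    reads = []
    for i in range(n_reads):
        sub, chrom, _ = units[choice[i]]
        L = lengths[chrom]
        rl = int(min(read_lengths[i], L // 2))
        start = int(rng.integers(0, L - rl))
        obs = []
        if chrom in var_by_chrom:
            vt = var_by_chrom[chrom]
            lo = int(np.searchsorted(vt.pos.values, start))
            hi = int(np.searchsorted(vt.pos.values, start + rl))
            for j in range(lo, hi):
                allele = sub
                if variant_error_rate and rng.random() < variant_error_rate:
                    allele = _other(sub)
                obs.append((vt.var_id.iloc[j], allele))
        reads.append(
            ReadObservation(
                read_id=f"{truth.line_id}.r{i:06d}",
                true_origin=sub,
                length=rl,
                observed_alleles=obs,
            )
        )
    return reads


def _chrom_mean_copies(self: HybridTruth, sub: str, chrom: str) -> float:
    segs = self.cn_profiles[sub][chrom]
    total = sum((e - s) * c for s, e, c in segs)
    length = sum(e - s for s, e, c in segs)
    return total / length if length else 0.0


HybridTruth.chrom_mean_copies = _chrom_mean_copies


def simulate_depth(
    truth: HybridTruth,
    mean_depth: float = 30.0,
    noise_sd: float = 0.0,
    window: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per-window depth tracks for each subgenome, on parental coordinates.

    Window depth is ``mean_depth x haplotype copies`` at the window midpoint
    plus Gaussian noise, floored at zero — the summary a read-mapping depth
    profile would give after windowing.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    tracks = {}
    for sub in ("P1", "P2"):
        rows = []
        for chrom, L in truth.pair.genome(sub).lengths().items():
            starts = np.arange(0, L, window)
            ends = np.minimum(starts + window, L)
            mids = (starts + ends) // 2
            copies = np.array(
                [truth.copies_at(sub, chrom, int(m)) for m in mids], dtype=float
            )
            depth = mean_depth * copies
            if noise_sd > 0:
                depth = depth + rng.normal(0.0, noise_sd, size=len(depth))
            depth = np.maximum(depth, 0.0)
            for s, e, d in zip(starts, ends, depth):
                rows.append((chrom, int(s), int(e), float(d)))
        tracks[sub] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "depth"]
        )
    return tracks


def simulate_fluctuation_cultures(
    mu: float,
    n0: int = 500,
    nt: int = 1_000_000,
    n_cultures: int = 48,
    seed: int = 0,
) -> np.ndarray:
    """Mutant counts for parallel cultures grown from ``n0`` to ``nt`` cells.

    Growth proceeds by discrete doublings; at each generation the number of
    new mutations is binomial in the non-mutant cells with per-cell
    per-generation probability ``mu``. Each mutant clone then expands from a
    random time within its birth generation (exponential-growth waiting
    time), which reproduces the 1/(k(k+1)) Luria-Delbruck clone-size law and
    hence the Lea-Coulson mutant-count distribution with
    ``m ~= mu * (nt - n0)``.
    """
    if not (0 < n0 < nt):
        raise ValueError("need 0 < n0 < nt")
    if mu < 0 or mu > 0.1:
        raise ValueError("mu must be a small non-negative rate")
    rng = np.random.default_rng(seed)
    n_gen = max(1, round(math.log2(nt / n0)))
    counts = np.zeros(n_cultures, dtype=np.int64)
    nonmut = np.full(n_cultures, n0, dtype=np.int64)
    for g in range(1, n_gen + 1):
        if mu == 0:
            nonmut *= 2
            continue
        k = rng.binomial(nonmut, mu)  # mutations among new daughters
        nonmut = 2 * nonmut - k
        d_left = n_gen - g  # full doublings remaining for new clones
        total = int(k.sum())
        if total == 0:
            continue
        owner = np.repeat(np.arange(n_cultures), k)
        u = rng.random(total)
        # within-generation birth time with exponential-growth density
        v = -np.log2(1.0 - u / 2.0)
        clone = np.floor(2.0 ** (d_left + v)).astype(np.int64)
        np.add.at(counts, owner, clone)
    return counts


# --------------------------------------------------------------------------
# Study-scale plan design and curation fixtures
# --------------------------------------------------------------------------


def design_study_plans(
    pair: ParentalPair, n_lines: int = 12, seed: int = 0
) -> list[SVPlan]:
    """A deterministic panel of evolved-line plans covering every SV class.

    The first lines each carry one archetypal event (polyploidy, aneuploidy
    gain and loss, LOH, truncation, excision, deletion, de novo insertion);
    later lines carry small mixtures or nothing, emulating the spread of a
    mutation-accumulation panel.
    """
    rng = np.random.default_rng(seed)
    elements = pair.elements
    fulls = elements[elements.completeness == "full-length"].reset_index(drop=True)
    lengths = pair.p1.lengths()
    chroms = list(lengths)
    # pick an LOH tract that contains at least one Ty locus
    target = fulls.iloc[2]
    loh_chrom = target.chrom
    tract_len = 400_000
    ls = max(int(target.start) - tract_len // 2, 10_000)
    le = min(ls + tract_len, lengths[loh_chrom] - 10_000)

    def locus(i):
        return fulls.locus_id.iloc[i % len(fulls)]

    def chrom(i):
        return chroms[i % len(chroms)]

    plans = []
    archetypes = [
        [SVEvent("polyploidy", subgenome="P2", copies=2)],
        [SVEvent("aneuploidy", subgenome="P1", chrom=chrom(1), copies=2)],
        [SVEvent("aneuploidy", subgenome="P2", chrom=chrom(3), copies=0)],
        [SVEvent("loh", subgenome="P1", chrom=loh_chrom, start=ls, end=le)],
        [SVEvent("truncation", subgenome="P1", locus_id=locus(4))],
        [SVEvent("excision", subgenome="P2", locus_id=locus(5))],
        [SVEvent("deletion", subgenome="P1", locus_id=locus(6))],
        [SVEvent("denovo", subgenome="P2", tsd_length=5)],
        [
            SVEvent("denovo", subgenome="P1", tsd_length=6),
            SVEvent("excision", subgenome="P1", locus_id=locus(7)),
        ],
        [
            SVEvent("aneuploidy", subgenome="P1", chrom=chrom(5), copies=2),
            SVEvent("truncation", subgenome="P2", locus_id=locus(8)),
        ],
        [SVEvent("deletion", subgenome="P2", locus_id=locus(9))],
        [],
    ]
    for i in range(n_lines):
        events = archetypes[i % len(archetypes)]
        plans.append(SVPlan(events=list(events), line_id=f"line{i + 1:02d}"))
    return plans


def make_curation_fixture(
    n_confirmed: int = 18,
    n_no_tsd: int = 2,
    n_dup_tsd: int = 2,
    n_dup_junction: int = 1,
    flank: int = 200,
    seed: int = 0,
):
    """Small parental genome plus de novo candidates with planted failures.

    Returns ``(candidates, parental_genomes, parental_tsds)`` where
    ``candidates`` is a list of dicts with locus id, flank sequences and the
    planted expectation (confirmed / rejected with which reason). Failure
    modes: no detectable TSD (flanks share only a 4-mer), a TSD motif reused
    from a parental full-length element, and a junction context that occurs
    verbatim in a parental genome.
    """
    rng = np.random.default_rng(seed)
    genome_seq = _random_seq(rng, 200_000)
    # parental full-length TSDs
    parental_tsds = []
    for _ in range(6):
        k = int(rng.choice([5, 6]))
        parental_tsds.append(seq_to_str(_random_seq(rng, k)))

    candidates = []
    idx = 0

    def fresh_tsd(k):
        while True:
            t = seq_to_str(_random_seq(rng, k))
            if t not in parental_tsds:
                return t

    def add(status, reason, flank5, flank3):
        nonlocal idx
        idx += 1
        candidates.append(
            dict(
                locus_id=f"cand{idx:02d}",
                line_id=f"line{idx % 5:02d}",
                family="Ty1",
                flank5=flank5,
                flank3=flank3,
                expected_status=status,
                expected_reason=reason,
            )
        )

    for i in range(n_confirmed):
        k = 5 if i % 2 == 0 else 6
        tsd = fresh_tsd(k)
        left = seq_to_str(_random_seq(rng, flank - k)) + tsd
        right = tsd + seq_to_str(_random_seq(rng, flank - k))
        add("confirmed", "", left, right)
    for _ in range(n_no_tsd):
        four = seq_to_str(_random_seq(rng, 4))
        left = seq_to_str(_random_seq(rng, flank - 4)) + four
        right = four + seq_to_str(_random_seq(rng, flank - 4))
        # avoid an accidental 5th matching base
        if left[-5] == right[4]:
            right = right[:4] + ("A" if right[4] != "A" else "C") + right[5:]
        add("rejected", "no_tsd", left, right)
    for _ in range(n_dup_tsd):
        tsd = parental_tsds[int(rng.integers(len(parental_tsds)))]
        left = seq_to_str(_random_seq(rng, flank - len(tsd))) + tsd
        right = tsd + seq_to_str(_random_seq(rng, flank - len(tsd)))
        add("rejected", "non_unique_tsd", left, right)
    for _ in range(n_dup_junction):
        k = 5
        tsd = fresh_tsd(k)
        pos = int(rng.integers(50_000, 150_000))
        ctx_left = seq_to_str(genome_seq[pos - (flank - k) : pos])
        ctx_right = seq_to_str(genome_seq[pos : pos + flank - k])
        # the doubled-TSD junction context occurs verbatim in the parental
        # genome — the signature of a pre-existing (polymorphic) insertion
        left = ctx_left + tsd
        right = tsd + ctx_right
        patched = np.concatenate(
            [
                genome_seq[:pos],
                str_to_seq(tsd + tsd),
                genome_seq[pos:],
            ]
        )
        genome_seq = patched
        add("rejected", "non_unique_junction", left, right)

    parental_genomes = {"P0": Genome("P0", {"chr01": genome_seq})}
    return candidates, parental_genomes, parental_tsds
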