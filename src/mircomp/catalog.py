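"""miRNA catalog construction.

Mature miRNAs from all species are grouped into families by single-linkage
over pairwise Smith-Waterman similarity, families are split into genes by
the 7-nt seed (nucleotides 2-8 from the 5' end), genes are classified by
their phylogenetic presence pattern, annotated against a reference mature
set, and single-gain (Dollo) gain/loss histories are inferred on the
species tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .tree import SpeciesTree, TreeError

RNA_CHARS = set("ACGU")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence from one species.

    The seed is nucleotides 2-8 (1-based, 5' end), the region whose
    identity defines isomiR groups.
    """

    id: str
    species: str
    sequence: str
    expression_rpm: float | None = None

    def __post_init__(self):
        if len(self.sequence) < 16:
            raise ValueError(f"{self.id}: mature sequence < 16 nt")
        if not set(self.sequence) <= RNA_CHARS:
            bad = sorted(set(self.sequence) - RNA_CHARS)
            raise ValueError(f"{self.id}: non-RNA characters {bad}")

    @property
    def seed(self) -> str:
        return self.sequence[1:8]


@dataclass(frozen=True)
class PreMiRNA:
    id: str
    species: str
    interval: object  # GenomicInterval
    mature_ids: tuple = ()


@dataclass
class FamilyAssignment:
    """family / gene / variability assignment for a set of matures."""

    family_of: dict[str, str]
    gene_of: dict[str, str] = field(default_factory=dict)
    variable: dict[str, bool] = field(default_factory=dict)  # per gene

    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for mid, gid in self.gene_of.items():
            out.setdefault(gid, []).append(mid)
        return out


DEFAULT_SCORING = (5, -4, -10, -4)  # match, mismatch, gap open, gap extend


def _aligner(scoring=DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    a = Align.PairwiseAligner(mode="local")
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def local_align_score(a: str, b: str, scoring=DEFAULT_SCORING):
    """Optimal Smith-Waterman local alignment under affine gaps.

    Returns ``(score, aligned_columns, identity)`` where identity is
    matches over aligned columns of the optimal alignment (first optimal
    alignment if several).  A pair with no positive-scoring alignment
    returns ``(0.0, 0, 0.0)``.
    """
    if not a or not b:
        raise ValueError("local_align_score requires non-empty sequences")
    aligner = _aligner(scoring)
    score = float(aligner.score(a, b))
    if score <= 0:
        return 0.0, 0, 0.0
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    columns = aln.length
    identity = counts.identities / columns if columns else 0.0
    return score, columns, identity


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def guaranteed_kmer(min_identity: float, min_cols: int, max_len: int) -> int:
    """Length of an exact match every qualifying alignment must contain.

    A local alignment with ``c`` columns and identity >= ``min_identity``
    has at most ``floor((1-min_identity)*c)`` non-match columns, which
    split at least ``ceil(min_identity*c)`` matches into runs; the longest
    run (a shared k-mer) is minimized over admissible ``c``.  Used as a
    provably lossless prefilter, not a heuristic.
    """
    best = None
    c_max = int(max_len / min_identity) + 1
    for c in range(min_cols, c_max + 1):
        matches = math.ceil(min_identity * c)
        bad = math.floor((1 - min_identity) * c)
        run = math.ceil(matches / (bad + 1))
        best = run if best is None else min(best, run)
    return max(best or 1, 1)


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def sequences_linked(
    a: str, b: str,
    min_identity: float = 0.85,
    min_cols: int = 16,
    scoring=DEFAULT_SCORING,
) -> bool:
    """Family-edge criterion on one sequence pair (optimal local alignment)."""
    if a == b:
        return True
    match, mismatch, gap_open, _ = scoring
    coef = min_identity * match + (1 - min_identity) * min(mismatch, gap_open)
    if coef > 0:
        if float(_aligner(scoring).score(a, b)) < min_cols * coef:
            return False
    _, cols, ident = local_align_score(a, b, scoring)
    return cols >= min_cols and ident >= min_identity


def build_families(
    matures: list[MatureMiRNA],
    min_identity: float = 0.85,
    min_cols: int = 16,
    scoring=DEFAULT_SCORING,
) -> FamilyAssignment:
    """Single-linkage families from all-against-all local alignment.

    An edge joins two matures when the optimal local alignment has
    identity >= ``min_identity`` over >= ``min_cols`` columns.  The family
    id is the lexicographically smallest member id, so assignment is
    independent of input order.

    Two lossless prefilters prune non-edges without changing the result:
    a qualifying pair must share an exact k-mer (:func:`guaranteed_kmer`)
    and must reach a score linear in ``min_cols`` when the per-column
    worst-case score of a qualifying alignment is positive.
    """
    if not matures:
        raise ValueError("build_families requires at least one mature")
    ids = [m.id for m in matures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mature ids")
    match, mismatch, gap_open, _ = scoring
    # worst per-column score of a qualifying alignment; only a valid prune
    # when positive (then score grows at least linearly in columns)
    coef = min_identity * match + (1 - min_identity) * min(mismatch, gap_open)
    score_bound = min_cols * coef if coef > 0 else -math.inf
    max_len = max(len(m.sequence) for m in matures)
    k = guaranteed_kmer(min_identity, min_cols, max_len)
    aligner = _aligner(scoring)
    uf = _UnionFind(ids)
    ordered = sorted(matures, key=lambda m: m.id)
    kmers = [_kmer_set(m.sequence, k) for m in ordered]
    for i, mi in enumerate(ordered):
        for j in range(i + 1, len(ordered)):
            mj = ordered[j]
            if mi.sequence == mj.sequence:
                uf.union(mi.id, mj.id)
                continue
            if not (kmers[i] & kmers[j]):
                continue
            if float(aligner.score(mi.sequence, mj.sequence)) < score_bound:
                continue
            _, cols, ident = local_align_score(mi.sequence, mj.sequence, scoring)
            if cols >= min_cols and ident >= min_identity:
                uf.union(mi.id, mj.id)
    components: dict[str, list[str]] = {}
    for mid in ids:
        components.setdefault(uf.find(mid), []).append(mid)
    family_of = {}
    for members in components.values():
        fam = min(members)
        for mid in members:
            family_of[mid] = fam
    return FamilyAssignment(family_of=family_of)


def assign_isomirs(
    assignment: FamilyAssignment, matures: list[MatureMiRNA]
) -> FamilyAssignment:
    """Split families into genes by identical seed; flag variable genes.

    Matures in the same family with the same 2-8 nt seed are isomiRs of
    one gene; a gene is *variable* when it carries at least two distinct
    mature sequences in any species (inter- and intra-species variants
    both count).
    """
    by_id = {m.id: m for m in matures}
    gene_members: dict[tuple[str, str], list[str]] = {}
    for mid, fam in assignment.family_of.items():
        key = (fam, by_id[mid].seed)
        gene_members.setdefault(key, []).append(mid)
    gene_of, variable = {}, {}
    for (fam, seed), members in gene_members.items():
        gid = f"{fam}:{seed}"
        seqs = {by_id[m].sequence for m in members}
        for mid in members:
            gene_of[mid] = gid
        variable[gid] = len(seqs) >= 2
    assignment.gene_of = gene_of
    assignment.variable = variable
    return assignment


@dataclass
class ConservationClass:
    class_of: dict[str, str]  # gene -> conserved | non-conserved | species-specific
    presence: dict[str, set]  # gene -> species set

    def counts(self) -> dict[str, int]:
        out = {"conserved": 0, "non-conserved": 0, "species-specific": 0}
        for c in self.class_of.values():
            out[c] += 1
        return out


def classify_conservation(
    gene_species: dict[str, set], tree: SpeciesTree
) -> ConservationClass:
    """Classify each gene by its presence pattern over the tree tips.

    conserved = present in every tip; species-specific = present in
    exactly one; everything else is non-conserved.
    """
    tips = set(tree.tip_names)
    class_of = {}
    for gene, species in gene_species.items():
        if not species:
            raise ValueError(f"gene {gene} has no species")
        extra = species - tips
        if extra:
            raise TreeError(
                f"gene {gene}: species not on tree: {', '.join(sorted(extra))}"
            )
        if species == tips:
            class_of[gene] = "conserved"
        elif len(species) == 1:
            class_of[gene] = "species-specific"
        else:
            class_of[gene] = "non-conserved"
    return ConservationClass(class_of=class_of,
                             presence={g: set(s) for g, s in gene_species.items()})


def gene_species_map(
    assignment: FamilyAssignment, matures: list[MatureMiRNA]
) -> dict[str, set]:
    by_id = {m.id: m for m in matures}
    out: dict[str, set] = {}
    for mid, gid in assignment.gene_of.items():
        out.setdefault(gid, set()).add(by_id[mid].species)
    return out


def annotate_known(
    gene_members: dict[str, list[MatureMiRNA]],
    reference: dict[str, str],
    min_identity: float = 0.9,
    scoring=DEFAULT_SCORING,
) -> dict[str, str]:
    """Label each gene known/novel against a reference mature set.

    A gene is *known* when any member locally aligns to any reference
    mature with identities covering >= ``min_identity`` of the shorter
    sequence's full length.
    """
    if not reference:
        raise ValueError("empty reference set")
    aligner = _aligner(scoring)
    out = {}
    for gid, members in gene_members.items():
        known = False
        for m in members:
            for ref_seq in reference.values():
                shorter = min(len(m.sequence), len(ref_seq))
                if aligner.score(m.sequence, ref_seq) <= 0:
                    continue
                aln = next(iter(aligner.align(m.sequence, ref_seq)))
                if aln.counts().identities / shorter >= min_identity:
                    known = True
                    break
            if known:
                break
        out[gid] = "known" if known else "novel"
    return out


def known_share(class_of: dict[str, str], status: dict[str, str]):
    """Fraction of conserved genes with a known (reference) homolog.

    Returns ``(n_known, n_conserved, pct)`` with pct rounded to the
    nearest integer percent, or None when no gene is conserved.
    """
    cons = [g for g, c in class_of.items() if c == "conserved"]
    n_known = sum(1 for g in cons if status.get(g) == "known")
    pct = round(100.0 * n_known / len(cons)) if cons else None
    return n_known, len(cons), pct


def dollo_gain_loss(tree: SpeciesTree, presence: dict[str, bool]):
    """Single-gain (Dollo) parsimony for one presence/absence character.

    The gain is placed on the branch above the MRCA of the present tips;
    losses are the maximal branches inside that clade whose subtree holds
    no present tip.  Returns ``(gain_branch, loss_branches, n_events)``.
    """
    present = sorted(t for t, v in presence.items() if v)
    if not present:
        raise ValueError("dollo_gain_loss: no present tips")
    unknown = [t for t in presence if t not in tree.tip_names]
    if unknown:
        raise TreeError(f"tips not on tree: {', '.join(unknown)}")
    mrca = tree.mrca(present)
    present_set = set(present)
    losses: list[str] = []

    def descend(node):
        for child in node.child_nodes():
            tips_below = {l.taxon.label for l in child.leaf_iter()}
            if tips_below & present_set:
                descend(child)
            else:
                losses.append(tree.node_id(child))

    descend(mrca)
    return tree.node_id(mrca), sorted(losses), 1 + len(losses)


def variability_table(
    classes: ConservationClass, assignment: FamilyAssignment
):
    """2x2 counts of variable/non-variable by conserved/species-specific.

    Returns ``(table, row_percentages)`` where the table rows are
    (conserved, species-specific) and columns (variable, non-variable);
    percentages are to one decimal, NaN for an empty class.
    """
    counts = np.zeros((2, 2), dtype=int)
    for gene, cls in classes.class_of.items():
        if cls == "conserved":
            row = 0
        elif cls == "species-specific":
            row = 1
        else:
            continue
        col = 0 if assignment.variable.get(gene, False) else 1
        counts[row, col] += 1
    pct = []
    for row in counts:
        total = row.sum()
        pct.append(round(100.0 * row[0] / total, 1) if total else math.nan)
    return counts, pct
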