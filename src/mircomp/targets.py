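"""Seed-match target prediction on aligned 3' UTRs and site statistics.

The matcher implements the canonical site hierarchy.  Writing the target
5'->3', a site is built around the reverse complement of miRNA nucleotides
2-7 (the 6mer core); an additional match to nucleotide 8 extends the site
one base 5' on the target (7mer-m8), an adenosine opposite nucleotide 1
extends it 3' (7mer-A1), and both together give the 8mer.  At each core
locus only the strongest available type is reported
(8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import Alignment, ungapped_to_columns

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def revcomp(rna: str) -> str:
    return rna.translate(_COMPLEMENT)[::-1]


def site_strings(mirna_sequence: str) -> dict[str, str]:
    """The four target match strings of a miRNA (target written 5'->3')."""
    m = mirna_sequence
    if len(m) < 8:
        raise ValueError("miRNA sequence must be >= 8 nt")
    core = revcomp(m[1:7])  # pairs nucleotides 2-7
    m8 = m[7].translate(_COMPLEMENT)  # pairs nucleotide 8
    return {
        "6mer": core,
        "7mer-m8": m8 + core,
        "7mer-A1": core + "A",
        "8mer": m8 + core + "A",
    }


@dataclass
class TargetSite:
    gene_id: str
    species: str
    mirna_id: str
    site_type: str
    start: int  # 0-based ungapped UTR offset
    length: int
    alignment_cols: tuple[int, int] | None = None  # first, last column
    relative_position: float | None = None
    conserved_site: bool | None = None


def find_seed_sites(utr: str, mirna_id: str, mirna_sequence: str,
                    gene_id: str = "", species: str = "") -> list[TargetSite]:
    """Scan an ungapped UTR for seed-match sites of one miRNA.

    Each matching 6mer-core locus yields exactly one site of the strongest
    type supported by its flanks; distinct loci may overlap.
    """
    patt = site_strings(mirna_sequence)
    core = patt["6mer"]
    m8 = patt["7mer-m8"][0]
    sites = []
    q = utr.find(core)
    while q != -1:
        has_m8 = q > 0 and utr[q - 1] == m8
        has_a1 = q + 6 < len(utr) and utr[q + 6] == "A"
        if has_m8 and has_a1:
            stype, start, length = "8mer", q - 1, 8
        elif has_m8:
            stype, start, length = "7mer-m8", q - 1, 7
        elif has_a1:
            stype, start, length = "7mer-A1", q, 7
        else:
            stype, start, length = "6mer", q, 6
        sites.append(
            TargetSite(gene_id=gene_id, species=species, mirna_id=mirna_id,
                       site_type=stype, start=start, length=length)
        )
        q = utr.find(core, q + 1)
    return sites


def scan_alignment(
    gene_id: str,
    alignment: Alignment,
    mirnas_by_species: dict[str, Iterable[tuple[str, str]]],
) -> list[TargetSite]:
    """Find sites for every species of one gene alignment.

    ``mirnas_by_species`` maps species -> iterable of (mirna gene id,
    representative mature sequence).  Sites get alignment columns and
    relative positions attached; conservation flags are set afterwards by
    :func:`call_site_conservation`.
    """
    sites: list[TargetSite] = []
    for species, aligned in alignment.sequences.items():
        utr = aligned.replace("-", "")
        if not utr:
            continue
        colmap = ungapped_to_columns(aligned)
        for mirna_id, seq in mirnas_by_species.get(species, ()):  # sorted upstream
            for s in find_seed_sites(utr, mirna_id, seq, gene_id, species):
                s.alignment_cols = (colmap[s.start], colmap[s.start + s.length - 1])
                s.relative_position = relative_position(s.start, s.length, len(utr))
                sites.append(s)
    return sites


def call_site_conservation(
    sites: list[TargetSite], alignment: Alignment, min_overlap: int = 6
) -> None:
    """Flag sites whose seed window is shared by every aligned species.

    A site is conserved iff every species in the gene's alignment carries
    a site of the same miRNA gene whose seed-window columns overlap it by
    at least ``min_overlap`` columns.
    """
    species_in_aln = set(alignment.species)
    for s in sites:
        if s.species not in species_in_aln:
            raise ValueError(
                f"site species {s.species} absent from gene {s.gene_id} alignment"
            )
    by_mirna: dict[str, dict[str, list[TargetSite]]] = {}
    for s in sites:
        by_mirna.setdefault(s.mirna_id, {}).setdefault(s.species, []).append(s)
    for mirna_id, per_species in by_mirna.items():
        for s in [x for v in per_species.values() for x in v]:
            lo, hi = s.alignment_cols
            conserved = True
            for other in species_in_aln:
                hits = per_species.get(other, [])
                if not any(
                    min(hi, o.alignment_cols[1]) - max(lo, o.alignment_cols[0]) + 1
                    >= min_overlap
                    for o in hits
                ):
                    conserved = False
                    break
            s.conserved_site = conserved


def relative_position(start: int, length: int, utr_length: int) -> float:
    """Site midpoint scaled to [0,1]; 0 at the stop codon, 1 at poly-A."""
    if utr_length < length:
        raise ValueError("UTR shorter than the site")
    if utr_length == length:
        return 0.5
    return (start + (length - 1) / 2) / (utr_length - 1)


def silverman_bandwidth(positions: np.ndarray) -> float:
    """R's default (nrd0) bandwidth: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    n = positions.size
    sd = positions.std(ddof=1)
    q75, q25 = np.percentile(positions, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread == 0:
        spread = sd
    if spread == 0:
        raise ValueError("all positions identical: bandwidth would be 0")
    return 0.9 * spread * n ** (-0.2)


def spatial_profile(relative_positions, n_grid: int = 512):
    """Gaussian KDE of relative site positions on an even [0,1] grid."""
    x = np.asarray(relative_positions, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("spatial_profile requires >= 2 distinct positions")
    bw = silverman_bandwidth(x)
    grid = np.linspace(0.0, 1.0, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * math.sqrt(2 * math.pi))
    return grid, density


def density_slope(grid, density, lo: float = 0.1, hi: float = 0.9):
    """OLS slope of the density restricted to positions in [lo, hi]."""
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 grid points in the regression window")
    slope, intercept = np.polyfit(grid[mask], density[mask], 1)
    return float(slope), float(intercept)


def split_by_length(utr_lengths: dict[str, float]):
    """Split genes at the median UTR length; long = strictly greater."""
    if len(utr_lengths) < 2:
        raise ValueError("need >= 2 genes")
    med = float(np.median(list(utr_lengths.values())))
    long_set = {g for g, l in utr_lengths.items() if l > med}
    short_set = set(utr_lengths) - long_set
    return long_set, short_set


@dataclass
class EmergenceRecord:
    gene_id: str
    n_species_specific_sites: int
    total_utr_length: int
    rate: float


def emergence_rates(
    sites: list[TargetSite],
    mirna_class_of: dict[str, str],
    utr_lengths: dict[str, dict[str, int]],
) -> list[EmergenceRecord]:
    """Species-specific target emergence rate per gene.

    rate = (species-specific sites summed over species) / (total 3' UTR
    length summed over species).  Genes without such sites get rate 0.
    """
    n_specific: dict[str, int] = {g: 0 for g in utr_lengths}
    for s in sites:
        if mirna_class_of.get(s.mirna_id) == "species-specific":
            n_specific[s.gene_id] = n_specific.get(s.gene_id, 0) + 1
    records = []
    for gene in sorted(utr_lengths):
        total = sum(utr_lengths[gene].values())
        if total <= 0:
            raise ValueError(f"gene {gene}: zero total UTR length")
        n = n_specific.get(gene, 0)
        records.append(EmergenceRecord(gene, n, total, n / total))
    return records


def select_top_fraction(records: list[EmergenceRecord], fraction: float = 0.05):
    """Top-emergence genes: sort by rate desc, gene id asc; take ceil(fN)."""
    if not records:
        raise ValueError("no emergence records")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ranked = sorted(records, key=lambda r: (-r.rate, r.gene_id))
    k = math.ceil(fraction * len(ranked))
    return [r.gene_id for r in ranked[:k]]


def target_counts_per_mirna(
    sites: list[TargetSite], mirna_ids: Iterable[str]
) -> dict[str, int]:
    """Total site count per miRNA gene, summed over genes and species."""
    counts = {m: 0 for m in mirna_ids}
    for s in sites:
        counts[s.mirna_id] = counts.get(s.mirna_id, 0) + 1
    return counts


def target_pattern_matrix(
    sites: list[TargetSite],
    conserved_mirnas: Iterable[str],
    genes: Iterable[str],
    species: Iterable[str],
):
    """Binary species x (miRNA, gene) presence matrix for PCA.

    Restricted to conserved miRNAs and the supplied orthologous gene set;
    an entry is 1 iff the species has at least one site for the pair.
    Returns ``(matrix features x samples, pair labels, species labels)``
    ready for :func:`mircomp.stats.pca`.
    """
    conserved = set(conserved_mirnas)
    gene_set = set(genes)
    species_list = sorted(species)
    pair_hits: dict[tuple[str, str], set] = {}
    for s in sites:
        if s.mirna_id in conserved and s.gene_id in gene_set:
            pair_hits.setdefault((s.mirna_id, s.gene_id), set()).add(s.species)
    pairs = sorted(pair_hits)
    matrix = np.zeros((len(pairs), len(species_list)))
    for i, pair in enumerate(pairs):
        for j, sp in enumerate(species_list):
            if sp in pair_hits[pair]:
                matrix[i, j] = 1.0
    return matrix, pairs, species_list
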