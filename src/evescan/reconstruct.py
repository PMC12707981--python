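"""Frameshift-aware protein-to-DNA alignment and degradation quantification.

A candidate locus is aligned against its best-hit reference protein by
dynamic programming over (aa position, nt position) with four step types:

* ``CODON`` — one protein residue against 3 nt, scored by the substitution
  matrix, or by ``stop_match_score`` when the codon is a stop (stops stay
  alignable so they can be counted);
* ``SHIFT`` — one protein residue against an irregular codon of 1, 2, 4 or
  5 nt at ``frameshift_penalty``; a single SHIFT therefore models a +-1 or
  +-2 frameshift while keeping the residue covered;
* ``DNA_GAP`` — an extra codon in the locus (insertion), affine-penalized;
* ``PROT_GAP`` — an unmatched protein residue (deletion in the locus),
  affine-penalized.

A gap of L steps costs ``gap_open + (L-1) * gap_extend``. Alignment is local:
paths may start fresh (score 0) before any CODON and the optimum is taken
over path ends. Traceback is deterministic under the move priority
CODON > SHIFT > DNA_GAP > PROT_GAP at equal score.

Introns are not modeled; long DNA_GAP runs simply appear as insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from numba import njit

from evescan._align import encode, load_matrix
from evescan.formats_io import SequenceRecord

__all__ = [
    "ReconstructParams",
    "ReconstructionAlignment",
    "ReconstructionReport",
    "frameshift_align",
    "reconstruct_locus",
    "quantify_changes",
]

NEG = -(10 ** 8)
_SHIFT_KS = (1, 2, 4, 5)


@dataclass(frozen=True)
class ReconstructParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 12
    gap_extend: int = 2
    frameshift_penalty: int = 20
    stop_match_score: int = -15
    coverage_floor: float = 0.8  # for the `intact` flag
    max_cells: int = 20_000_000  # DP size guard

    def __post_init__(self) -> None:
        if self.frameshift_penalty <= max(self.gap_open, self.gap_extend):
            raise ValueError("frameshift_penalty must exceed gap penalties")


@dataclass
class ReconstructionAlignment:
    """Traceback of the frameshift-aware DP.

    ``path`` steps (nt/aa positions 0-based, ascending):

    * ``("CODON", aa_pos, nt_pos, codon)``
    * ``("SHIFT", aa_pos, nt_pos, k)`` — k nt consumed
    * ``("DNA_GAP", nt_pos, codon)``
    * ``("PROT_GAP", aa_pos)``
    """

    protein_id: str
    locus_id: str
    path: list[tuple]
    raw_score: int
    reconstructed_peptide: str
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    protein_length: int
    strand: str = "+"


@dataclass(frozen=True)
class ReconstructionReport:
    n_stops: int
    n_insertions: int
    n_deletions: int
    n_frameshifts: int
    pident: float
    protein_coverage: float
    intact: bool


@njit(cache=True)
def _fs_fill(a, codon_aa, matrix, go, ge, fs, stop_score):  # pragma: no cover
    m = a.shape[0]
    n = codon_aa.shape[0] - 1
    C = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    D = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    P = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    ptrC = np.full((m + 1, n + 1), -1, dtype=np.int8)
    ptrF = np.full((m + 1, n + 1), -1, dtype=np.int8)
    kF = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrD = np.full((m + 1, n + 1), -1, dtype=np.int8)
    ptrP = np.full((m + 1, n + 1), -1, dtype=np.int8)
    half = NEG // 2

    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(n + 1):
            # CODON: consumes aa i, nt [j-3, j)
            if j >= 3:
                s = stop_score if codon_aa[j] < 0 else matrix[ai, codon_aa[j]]
                best = np.int32(0)
                ptr = np.int8(4)  # fresh start
                pi, pj = i - 1, j - 3
                if C[pi, pj] > best:
                    best = C[pi, pj]; ptr = np.int8(0)
                if F[pi, pj] > best:
                    best = F[pi, pj]; ptr = np.int8(1)
                if D[pi, pj] > best:
                    best = D[pi, pj]; ptr = np.int8(2)
                if P[pi, pj] > best:
                    best = P[pi, pj]; ptr = np.int8(3)
                C[i, j] = best + s
                ptrC[i, j] = ptr
            # SHIFT: consumes aa i, k nt
            bestf = np.int32(NEG)
            ptrf = np.int8(-1)
            kf = np.int8(0)
            for k in _SHIFT_KS:
                if j >= k:
                    pi, pj = i - 1, j - k
                    if C[pi, pj] > bestf:
                        bestf = C[pi, pj]; ptrf = np.int8(0); kf = np.int8(k)
                    if F[pi, pj] > bestf:
                        bestf = F[pi, pj]; ptrf = np.int8(1); kf = np.int8(k)
                    if D[pi, pj] > bestf:
                        bestf = D[pi, pj]; ptrf = np.int8(2); kf = np.int8(k)
                    if P[pi, pj] > bestf:
                        bestf = P[pi, pj]; ptrf = np.int8(3); kf = np.int8(k)
            if bestf > half:
                F[i, j] = bestf - fs
                ptrF[i, j] = ptrf
                kF[i, j] = kf
            # PROT_GAP: consumes aa i only
            bestp = np.int32(NEG)
            ptrp = np.int8(-1)
            if C[i - 1, j] - go > bestp:
                bestp = C[i - 1, j] - go; ptrp = np.int8(0)
            if F[i - 1, j] - go > bestp:
                bestp = F[i - 1, j] - go; ptrp = np.int8(1)
            if P[i - 1, j] - ge > bestp:
                bestp = P[i - 1, j] - ge; ptrp = np.int8(3)
            if bestp > half:
                P[i, j] = bestp
                ptrP[i, j] = ptrp
            # DNA_GAP: consumes nt [j-3, j) only (same row, earlier j)
            if j >= 3:
                bestd = np.int32(NEG)
                ptrd = np.int8(-1)
                if C[i, j - 3] - go > bestd:
                    bestd = C[i, j - 3] - go; ptrd = np.int8(0)
                if F[i, j - 3] - go > bestd:
                    bestd = F[i, j - 3] - go; ptrd = np.int8(1)
                if D[i, j - 3] - ge > bestd:
                    bestd = D[i, j - 3] - ge; ptrd = np.int8(2)
                if bestd > half:
                    D[i, j] = bestd
                    ptrD[i, j] = ptrd
    return C, F, D, P, ptrC, ptrF, kF, ptrD, ptrP


def _translate_codon(codon: str) -> str:
    if len(codon) != 3:
        return "X"
    return str(Seq(codon).translate())


def frameshift_align(protein: SequenceRecord, locus_dna: str,
                     params: ReconstructParams = ReconstructParams(),
                     locus_id: str = "locus") -> ReconstructionAlignment:
    """Optimal local frameshift-aware alignment of ``protein`` against the
    forward strand of ``locus_dna`` (strand resolution is the caller's job;
    see :func:`reconstruct_locus`)."""
    if not protein.seq:
        raise ValueError("empty protein")
    if len(locus_dna) < 3:
        raise ValueError("locus DNA shorter than one codon")
    m, n = len(protein.seq), len(locus_dna)
    if (m + 1) * (n + 1) > params.max_cells:
        raise ValueError(
            f"DP size {(m + 1) * (n + 1)} cells exceeds the guard "
            f"({params.max_cells}); band the locus or raise max_cells"
        )

    alphabet, matrix = load_matrix(params.matrix)
    a = encode(protein.seq, alphabet)
    dna = locus_dna.upper()
    codon_aa = np.full(n + 1, -2, dtype=np.int32)
    for j in range(3, n + 1):
        aa = _translate_codon(dna[j - 3:j])
        codon_aa[j] = -1 if aa == "*" else alphabet.index(aa if aa in alphabet else "X")

    C, F, D, P, ptrC, ptrF, kF, ptrD, ptrP = _fs_fill(
        a, codon_aa, matrix,
        np.int32(params.gap_open), np.int32(params.gap_extend),
        np.int32(params.frameshift_penalty), np.int32(params.stop_match_score),
    )

    best = int(C.max())
    if best <= 0:
        return ReconstructionAlignment(protein.id, locus_id, [], 0, "",
                                       0, 0, 0, 0, m)
    flat = int(np.argmax(C))
    i, j = divmod(flat, n + 1)
    aa_end, nt_end = i, j

    steps: list[tuple] = []
    state = 0  # 0=C, 1=F, 2=D, 3=P
    while True:
        if state == 0:
            codon = dna[j - 3:j]
            steps.append(("CODON", i - 1, j - 3, codon))
            pred = int(ptrC[i, j])
            i, j = i - 1, j - 3
            if pred == 4:
                break
            state = pred
        elif state == 1:
            k = int(kF[i, j])
            steps.append(("SHIFT", i - 1, j - k, k))
            pred = int(ptrF[i, j])
            i, j = i - 1, j - k
            state = pred
        elif state == 2:
            steps.append(("DNA_GAP", j - 3, dna[j - 3:j]))
            pred = int(ptrD[i, j])
            j = j - 3
            state = pred
        else:
            steps.append(("PROT_GAP", i - 1))
            pred = int(ptrP[i, j])
            i = i - 1
            state = pred
    steps.reverse()

    peptide_parts = []
    for step in steps:
        if step[0] == "CODON":
            peptide_parts.append(_translate_codon(step[3]))
        elif step[0] == "SHIFT":
            peptide_parts.append("X")
        elif step[0] == "DNA_GAP":
            peptide_parts.append(_translate_codon(step[2]))
    return ReconstructionAlignment(
        protein_id=protein.id,
        locus_id=locus_id,
        path=steps,
        raw_score=best,
        reconstructed_peptide="".join(peptide_parts),
        aa_start=i,
        aa_end=aa_end,
        nt_start=j,
        nt_end=nt_end,
        protein_length=m,
    )


def reconstruct_locus(protein: SequenceRecord, locus_dna: str,
                      params: ReconstructParams = ReconstructParams(),
                      locus_id: str = "locus") -> ReconstructionAlignment:
    """Align against both strands of the locus and keep the better score
    (ties favour '+')."""
    fwd = frameshift_align(protein, locus_dna, params, locus_id)
    rev = frameshift_align(protein, str(Seq(locus_dna).reverse_complement()),
                           params, locus_id)
    if rev.raw_score > fwd.raw_score:
        rev.strand = "-"
        return rev
    return fwd


def _validate_path(path: Sequence[tuple]) -> None:
    last_nt = last_aa = -1
    for step in path:
        kind = step[0]
        if kind in ("CODON", "SHIFT"):
            aa_pos, nt_pos = step[1], step[2]
            if aa_pos <= last_aa or nt_pos < last_nt:
                raise ValueError("malformed path: positions not increasing")
            last_aa, last_nt = aa_pos, nt_pos
        elif kind == "DNA_GAP":
            if step[1] < last_nt:
                raise ValueError("malformed path: nt positions not increasing")
            last_nt = step[1]
        elif kind == "PROT_GAP":
            if step[1] <= last_aa:
                raise ValueError("malformed path: aa positions not increasing")
            last_aa = step[1]
        else:
            raise ValueError(f"malformed path: unknown step {kind!r}")


def quantify_changes(alignment: ReconstructionAlignment,
                     protein_seq: str | None = None,
                     params: ReconstructParams = ReconstructParams()) -> ReconstructionReport:
    """Count degradation events by rescanning the alignment path.

    ``pident`` is computed over CODON steps only (translated codon vs protein
    residue, which requires ``protein_seq``); ``protein_coverage`` is the
    fraction of protein residues matched by CODON or SHIFT steps.
    """
    _validate_path(alignment.path)
    n_stops = n_ins = n_del = n_shift = n_codon = n_ident = 0
    for step in alignment.path:
        kind = step[0]
        if kind == "CODON":
            n_codon += 1
            aa = _translate_codon(step[3])
            if aa == "*":
                n_stops += 1
            if protein_seq is not None and aa == protein_seq[step[1]]:
                n_ident += 1
        elif kind == "SHIFT":
            n_shift += 1
        elif kind == "DNA_GAP":
            n_ins += 1
        elif kind == "PROT_GAP":
            n_del += 1
    pident = 100.0 * n_ident / n_codon if (n_codon and protein_seq is not None) else 0.0
    coverage = (n_codon + n_shift) / alignment.protein_length if alignment.protein_length else 0.0
    intact = (n_stops == 0 and n_shift == 0 and coverage >= params.coverage_floor)
    return ReconstructionReport(
        n_stops=n_stops,
        n_insertions=n_ins,
        n_deletions=n_del,
        n_frameshifts=n_shift,
        pident=pident,
        protein_coverage=coverage,
        intact=intact,
    )
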