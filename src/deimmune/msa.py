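"""Family alignment handling: focus columns, gap filtering, reweighting,
site frequencies and candidate substitution sets.

The alignment is reduced to *focus columns* — the columns in which the
target sequence has a residue — and every downstream quantity (weights,
frequencies, the Potts model, the design region) is indexed by those
columns. Position ``i`` (1-based) corresponds to residue
``target_offset + i - 1`` in protein numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import AA20, AA_GAP, GAP, clean_symbol

_GAP_IDX = AA_GAP.index(GAP)


@dataclass
class Alignment:
    """A family MSA reduced to the target's focus columns.

    ``matrix`` holds the cleaned focus-column characters (N x L); ``weights``
    is filled by :func:`sequence_weights` and defaults to None.
    """

    ids: list[str]
    matrix: np.ndarray  # (N, L) of single characters over AA_GAP
    focus_columns: np.ndarray  # indices into the original alignment columns
    target_id: str
    target_offset: int = 1
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids and matrix row count disagree")
        fc = np.asarray(self.focus_columns)
        if fc.size > 1 and not np.all(np.diff(fc) > 0):
            raise ValueError("focus columns must be strictly increasing")

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def meff(self) -> float:
        if self.weights is None:
            raise ValueError("weights not computed; call sequence_weights first")
        return float(np.sum(self.weights))

    @property
    def target_index(self) -> int:
        return self.ids.index(self.target_id)

    @property
    def target_sequence(self) -> str:
        return "".join(self.matrix[self.target_index])

    def encoded(self) -> np.ndarray:
        """Integer encoding over AA_GAP (gap = 20)."""
        lut = np.full(128, _GAP_IDX, dtype=np.int64)
        for i, c in enumerate(AA_GAP):
            lut[ord(c)] = i
        codes = np.ascontiguousarray(self.matrix).view(np.uint32).reshape(self.matrix.shape)
        return lut[codes.astype(np.int64) & 0x7F]

    def position_to_residue(self, i: int) -> int:
        """1-based focus position -> protein residue number."""
        return self.target_offset + i - 1


@dataclass
class SiteFrequencies:
    """Weighted per-position symbol frequencies over AA_GAP (gap included)."""

    f: np.ndarray  # (L, 21)
    alphabet: str = AA_GAP

    @property
    def L(self) -> int:
        return self.f.shape[0]


@dataclass
class MutationSets:
    """Allowed substitutions per position, plus the wild type they extend."""

    M: list[list[str]]
    wild_type: str
    zeta: float
    mutable_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for i, opts in enumerate(self.M):
            if not opts:
                raise ValueError(f"empty substitution set at position {i + 1}")
            if self.wild_type[i] not in opts:
                raise ValueError(f"wild type excluded at position {i + 1}")

    @property
    def n(self) -> int:
        return len(self.M)


def read_alignment(path, fmt: str = "fasta", target_id: str | None = None,
                   target_offset: int = 1) -> Alignment:
    """Read an MSA and reduce it to the target's focus columns.

    For FASTA/Stockholm the focus columns are those where the target record
    carries a residue; for A2M they are the match columns the target
    occupies (upper-case states). ``target_id`` matches the record id or its
    first '/'-delimited token.
    """
    if fmt not in {"fasta", "a2m", "stockholm"}:
        raise ValueError(f"unsupported format {fmt!r}")
    with open(path) as fh:
        if fmt == "stockholm":
            records = list(AlignIO.read(fh, "stockholm"))
        else:
            records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent sequence lengths: {sorted(lengths)}")

    ids = [r.id for r in records]
    if target_id is None:
        target_id = ids[0]
    matches = [i for i, rid in enumerate(ids)
               if rid == target_id or rid.split("/")[0] == target_id]
    if not matches:
        raise ValueError(f"target record {target_id!r} not found")
    tgt = str(records[matches[0]].seq)

    if fmt == "a2m":
        focus = np.array([j for j, c in enumerate(tgt) if c.isupper() and c != "."],
                         dtype=np.int64)
    else:
        focus = np.array([j for j, c in enumerate(tgt)
                          if clean_symbol(c) != GAP], dtype=np.int64)
    if focus.size == 0:
        raise ValueError("target sequence is all gaps")

    raw = np.array([list(str(r.seq)) for r in records])
    sub = raw[:, focus]
    cleaned = np.vectorize(clean_symbol)(sub)
    return Alignment(ids=ids, matrix=cleaned, focus_columns=focus,
                     target_id=ids[matches[0]], target_offset=target_offset)


def filter_alignment(aln: Alignment, max_row_gap: float = 0.7,
                     max_col_gap: float = 0.5) -> Alignment:
    """Drop gappy sequences and columns.

    Sequences with a gap fraction >= ``max_row_gap`` over the current focus
    columns and columns with a gap fraction > ``max_col_gap`` are removed,
    iterating to a fixed point so the returned alignment satisfies both
    bounds simultaneously (which also makes the operation idempotent).
    The target record is never removed.
    """
    if not (0 < max_row_gap <= 1 and 0 < max_col_gap <= 1):
        raise ValueError("gap thresholds must lie in (0, 1]")
    ids = list(aln.ids)
    mat = aln.matrix
    focus = np.asarray(aln.focus_columns)
    tgt = aln.target_id
    while True:
        if mat.shape[0] == 0 or mat.shape[1] == 0:
            raise ValueError("filtering removed the whole alignment")
        gaps = mat == GAP
        row_frac = gaps.mean(axis=1)
        keep_rows = row_frac < max_row_gap
        keep_rows[ids.index(tgt)] = True
        if not np.all(keep_rows):
            mat = mat[keep_rows]
            ids = [i for i, k in zip(ids, keep_rows) if k]
            continue
        col_frac = gaps.mean(axis=0)
        keep_cols = col_frac <= max_col_gap
        if not np.all(keep_cols):
            mat = mat[:, keep_cols]
            focus = focus[keep_cols]
            continue
        break
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("filtering removed the whole alignment")
    return Alignment(ids=ids, matrix=mat, focus_columns=focus,
                     target_id=tgt, target_offset=aln.target_offset)


def sequence_weights(aln: Alignment, theta: float = 0.9,
                     chunk: int = 512) -> Alignment:
    """Inverse-cluster-size reweighting at identity threshold ``theta``.

    Identity between two sequences is the fraction of focus columns where
    both carry the same residue; any position involving a gap counts as a
    mismatch. Each sequence's weight is 1 over the number of sequences
    (itself included) at identity >= theta; Meff is the weight sum.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must lie in (0, 1]")
    if aln.N == 0:
        raise ValueError("empty alignment")
    enc = aln.encoded()
    is_res = enc != _GAP_IDX
    L = aln.L
    counts = np.zeros(aln.N, dtype=np.int64)
    for start in range(0, aln.N, chunk):
        blk = enc[start:start + chunk]
        blk_res = is_res[start:start + chunk]
        # matches[s, t] = #cols where both non-gap and equal
        eq = (blk[:, None, :] == enc[None, :, :]) & blk_res[:, None, :] & is_res[None, :, :]
        ident = eq.sum(axis=2) / L
        for r in range(blk.shape[0]):  # self always counts as a cluster member
            ident[r, start + r] = 1.0
        counts[start:start + chunk] = (ident >= theta).sum(axis=1)
    weights = 1.0 / counts
    return replace(aln, weights=weights)


def site_frequencies(aln: Alignment) -> SiteFrequencies:
    """Weighted relative symbol frequencies per focus column (gap included)."""
    if aln.weights is None:
        raise ValueError("weights not computed; call sequence_weights first")
    enc = aln.encoded()
    q = len(AA_GAP)
    f = np.zeros((aln.L, q))
    for a in range(q):
        f[:, a] = ((enc == a) * aln.weights[:, None]).sum(axis=0)
    f /= f.sum(axis=1, keepdims=True)
    return SiteFrequencies(f=f)


def mutation_sets(freqs: SiteFrequencies, wild_type: str, zeta: float,
                  mutable_positions: set[int] | None = None) -> MutationSets:
    """Candidate substitutions: residues with (gap-renormalized) frequency
    >= zeta at mutable positions, the wild-type residue always included.

    ``mutable_positions`` are 1-based focus positions; positions outside it
    are pinned to the wild type. ``None`` makes every position mutable.
    """
    if not 0 <= zeta <= 1:
        raise ValueError("zeta must lie in [0, 1]")
    if len(wild_type) != freqs.L:
        raise ValueError("wild type length disagrees with frequencies")
    if mutable_positions is None:
        mutable_positions = set(range(1, freqs.L + 1))
    aa_f = freqs.f[:, :len(AA20)].copy()
    tot = aa_f.sum(axis=1, keepdims=True)
    np.divide(aa_f, tot, out=aa_f, where=tot > 0)
    M: list[list[str]] = []
    for i in range(freqs.L):
        wt = wild_type[i]
        if wt not in AA20:
            raise ValueError(f"wild type symbol {wt!r} at position {i + 1}")
        if (i + 1) in mutable_positions:
            # at zeta == 0 only residues actually observed qualify
            hit = (aa_f[i] >= zeta) & (aa_f[i] > 0)
            opts = {AA20[a] for a in np.nonzero(hit)[0]}
            opts.add(wt)
        else:
            opts = {wt}
        M.append(sorted(opts, key=AA20.index))
    return MutationSets(M=M, wild_type=wild_type, zeta=zeta,
                        mutable_positions=frozenset(mutable_positions))
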