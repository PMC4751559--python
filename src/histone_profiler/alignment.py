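"""Deterministic global pairwise alignment of histone variants to a reference.

Each variant is aligned to the mature human reference of its class with an
affine-gap Needleman–Wunsch (Gotoh) procedure; the resulting
reference→query position map is what the conservation scorer consumes.
Pairwise alignment to the class reference deliberately replaces a multiple
sequence alignment: the conservation statistic only needs each variant's
correspondence to the reference, and a pairwise procedure is deterministic
and reproducible down to its tie-breaking rules (prefer diagonal, then a
query-consuming gap, then a reference-consuming gap during traceback).

A gap opened against an *incomplete* terminus of the query is evidence
absence, not evidence of loss: such reference positions are mapped to the
``UNASSESSED`` sentinel and excluded from the N denominator downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .records import Completeness, ProteinRecord

__all__ = [
    "SubstitutionMatrix",
    "load_matrix",
    "blosum62",
    "AlignmentResult",
    "global_align",
    "map_reference_positions",
    "UNASSESSED",
    "local_hits",
]

NEG_INF = float("-inf")


class _Unassessed:
    """Sentinel for reference positions that an incomplete assembly cannot inform."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNASSESSED"


UNASSESSED = _Unassessed()


class SubstitutionMatrix:
    """Protein substitution scores read from an NCBI-format matrix file."""

    def __init__(self, scores: dict[tuple[str, str], float]):
        self.scores = scores
        self.worst = min(scores.values())

    def score(self, a: str, b: str) -> float:
        """Pairwise score; residues absent from the matrix behave as X,
        and if X itself is absent the worst matrix entry is used."""
        for pair in ((a, b), ("X", b) if (a, b) not in self.scores else (a, b)):
            if pair in self.scores:
                return self.scores[pair]
        if (a, "X") in self.scores:
            return self.scores[(a, "X")]
        if ("X", "X") in self.scores:
            return self.scores[("X", "X")]
        return self.worst


def load_matrix(path: str | Path) -> SubstitutionMatrix:
    """Parse an NCBI-format substitution matrix (e.g. the bundled BLOSUM62)."""
    columns: list[str] = []
    scores: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not columns:
                columns = fields
                continue
            row = fields[0]
            for col, val in zip(columns, fields[1:]):
                scores[(row, col)] = float(val)
    if not columns:
        raise ValueError(f"{path}: no matrix data found")
    return SubstitutionMatrix(scores)


def blosum62() -> SubstitutionMatrix:
    """The bundled BLOSUM62 matrix."""
    with resources.as_file(
        resources.files("histone_profiler.data") / "blosum62.txt"
    ) as p:
        return load_matrix(p)


@dataclass
class AlignmentResult:
    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned strings must have equal length")

    @property
    def query_sequence(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference_sequence(self) -> str:
        return self.aligned_reference.replace("-", "")

    def ref_to_query(self) -> dict[int, int | None]:
        """1-based reference position → 1-based query position, or None at gaps."""
        out: dict[int, int | None] = {}
        qpos = rpos = 0
        for qc, rc in zip(self.aligned_query, self.aligned_reference):
            if qc != "-":
                qpos += 1
            if rc != "-":
                rpos += 1
                out[rpos] = qpos if qc != "-" else None
        return out


def global_align(
    query: str | ProteinRecord,
    reference: str | ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment under affine gap penalties.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  The
    traceback is fully deterministic: on score ties a substitution column is
    preferred over a query-consuming gap, which is preferred over a
    reference-consuming gap, and within gap states the predecessor state is
    chosen in the same fixed order.
    """
    qid = query.id if isinstance(query, ProteinRecord) else "query"
    rid = reference.id if isinstance(reference, ProteinRecord) else "reference"
    x = query.sequence if isinstance(query, ProteinRecord) else query
    y = reference.sequence if isinstance(reference, ProteinRecord) else reference
    if not x or not y:
        raise ValueError("both sequences must be non-empty")
    if not (gap_open <= gap_extend <= 0):
        raise ValueError("expected gap_open <= gap_extend <= 0")
    if matrix is None:
        matrix = blosum62()

    m, n = len(x), len(y)
    # state 0 = M (substitution), 1 = X (gap in reference, consumes query),
    # 2 = Y (gap in query, consumes reference)
    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend

    for i in range(1, m + 1):
        xi = x[i - 1]
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, n + 1):
            s = matrix.score(xi, y[j - 1])
            row_m[j] = s + max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            row_x[j] = max(
                prev_m[j] + gap_open, prev_x[j] + gap_extend, prev_y[j] + gap_open
            )
            row_y[j] = max(
                row_m[j - 1] + gap_open, row_x[j - 1] + gap_open, row_y[j - 1] + gap_extend
            )

    tables = (M, X, Y)
    # final state: ties resolved M > X > Y
    state = max(range(3), key=lambda s: (tables[s][m][n], -s))
    score = tables[state][m][n]

    aq: list[str] = []
    ar: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            s = matrix.score(x[i - 1], y[j - 1])
            cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - s
            state = _pick(cands, target)
            aq.append(x[i - 1])
            ar.append(y[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            cands = (
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            state = _pick(cands, X[i][j])
            aq.append(x[i - 1])
            ar.append("-")
            i -= 1
        else:
            cands = (
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
            )
            state = _pick(cands, Y[i][j])
            aq.append("-")
            ar.append(y[j - 1])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1

    return AlignmentResult(
        query_id=qid,
        reference_id=rid,
        aligned_query="".join(reversed(aq)),
        aligned_reference="".join(reversed(ar)),
        score=score,
    )


def _pick(candidates: tuple[float, float, float], target: float) -> int:
    for idx, value in enumerate(candidates):
        if abs(value - target) < 1e-9:
            return idx
    raise AssertionError("traceback inconsistency")  # pragma: no cover


def map_reference_positions(
    aln: AlignmentResult, query_completeness: Completeness
) -> dict[int, int | None | _Unassessed]:
    """Reference→query map with incomplete termini marked unassessed.

    Reference positions aligned to a query residue map to its 1-based index;
    positions opposite a gap map to ``None`` (counted against conservation)
    — except terminal gap runs on the query side when the corresponding query
    terminus is missing from the assembly (a 5'-incomplete query for the
    leading run; a 3'-incomplete or fragment query for the trailing run),
    which map to :data:`UNASSESSED` and are excluded from the N denominator.

    Global alignment of a truncated query occasionally places one or two of
    its terminal residues against a later (or earlier) reference residue
    instead of leaving a clean end gap — an artifact of end-gap placement,
    not evidence about the missing terminus.  The terminal run therefore
    absorbs such short islands: it extends inward until the first run of at
    least 3 consecutively aligned reference positions, and isolated matches
    inside it are marked unassessed as well.
    """
    base = aln.ref_to_query()
    result: dict[int, int | None | _Unassessed] = dict(base)
    positions = sorted(base)

    def terminal_run(ordered: list[int], anchor_run: int = 3) -> set[int]:
        out: set[int] = set()
        island: list[int] = []
        consecutive = 0
        for pos in ordered:
            if base[pos] is None:
                out.update(island)
                island = []
                consecutive = 0
                out.add(pos)
            else:
                consecutive += 1
                island.append(pos)
                if consecutive >= anchor_run:
                    break
        return out

    if query_completeness is Completeness.INCOMPLETE_5PRIME:
        for pos in terminal_run(positions):
            result[pos] = UNASSESSED
    if query_completeness in (Completeness.INCOMPLETE_3PRIME, Completeness.FRAGMENT):
        for pos in terminal_run(positions[::-1]):
            result[pos] = UNASSESSED
    return result


def local_hits(
    query: str, reference: str, min_coverage: float = 0.80, min_identity: float = 0.40
) -> list[tuple[int, int]]:
    """Mutually non-overlapping local hits of ``reference`` within ``query``.

    Smith–Waterman (via Bio.Align.PairwiseAligner, BLOSUM62, -11/-1) applied
    recursively: the best hit passing the reference-coverage and identity
    floors claims its query interval, then the flanking query segments are
    searched independently.  Returns 0-based half-open query intervals sorted
    by start.  This is the evidence collector behind misassembly flagging.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    def clean(s: str) -> str:
        return "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for c in s)

    def search(segment: str, offset: int, out: list[tuple[int, int]]) -> None:
        if len(segment) < max(1, int(min_coverage * len(reference))):
            return
        alignments = aligner.align(clean(segment), clean(reference))
        if len(alignments) == 0:
            return
        aln = alignments[0]
        qblocks, rblocks = aln.aligned
        if len(qblocks) == 0:
            return
        ref_covered = sum(b - a for a, b in rblocks)
        columns = matches = 0
        for (qa, qb), (ra, rb) in zip(qblocks, rblocks):
            for k in range(qb - qa):
                columns += 1
                if segment[qa + k] == reference[ra + k]:
                    matches += 1
        q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
        if ref_covered >= min_coverage * len(reference) and columns and (
            matches / columns >= min_identity
        ):
            out.append((offset + q_start, offset + q_end))
            search(segment[:q_start], offset, out)
            search(segment[q_end:], offset + q_end, out)

    hits: list[tuple[int, int]] = []
    search(query, 0, hits)
    return sorted(hits)
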