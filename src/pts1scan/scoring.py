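"""Tripeptide consensus matching and 12-residue PSSM scoring.

Two complementary views of PTS1 quality live here.  The *consensus*
view is the classical tripeptide pattern [S/A/C]-[K/R/H]-L at the
extreme C-terminus.  The *matrix* view scores the last 12 residues of
a protein with a position-specific scoring matrix (PSSM) and maps the
score onto three categories — "Targeted", "Twilight zone", "Not
targeted" — via two ordered thresholds.

The scoring-matrix coefficients of the original published predictor
are not public; the matrix is therefore configuration, read from a
strict TSV format, and the package ships a small documented example
matrix for tests and demonstrations plus an all-zero placeholder.
Published score *differences* from external predictor runs are
consumed as data by the concordance statistics, never recomputed from
the bundled example matrix.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

from .errors import MatrixFormatError, SequenceError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WINDOW_LENGTH = 12

TARGETED = "Targeted"
TWILIGHT = "Twilight zone"
NOT_TARGETED = "Not targeted"

# Classical PTS1 consensus: [S/A/C]-[K/R/H]-L at the C-terminus.
DEFAULT_CONSENSUS: Tuple[frozenset, frozenset, frozenset] = (
    frozenset("SAC"),
    frozenset("KRH"),
    frozenset("L"),
)


@dataclass(frozen=True)
class Pts1Matrix:
    """A 12 x 20 position-specific scoring matrix with category thresholds.

    ``entries[(position, residue)]`` is the additive score contribution
    of ``residue`` at 1-based ``position`` (1 = most N-terminal of the
    12-residue window, 12 = C-terminal residue).  ``t_targeted`` and
    ``t_twilight`` split the score axis into the three categories;
    ``t_targeted > t_twilight`` always.
    """

    entries: Dict[Tuple[int, str], float]
    t_targeted: float
    t_twilight: float
    name: str = "unnamed"

    def __post_init__(self):
        if not self.t_targeted > self.t_twilight:
            raise MatrixFormatError(
                f"thresholds must satisfy t_targeted > t_twilight "
                f"(got {self.t_targeted} <= {self.t_twilight})"
            )
        expected = {(p, aa) for p in range(1, WINDOW_LENGTH + 1) for aa in AMINO_ACIDS}
        if set(self.entries) != expected:
            missing = expected - set(self.entries)
            extra = set(self.entries) - expected
            raise MatrixFormatError(
                f"matrix must define every (position, residue) pair exactly once; "
                f"missing {len(missing)}, unexpected {len(extra)}"
            )


@dataclass(frozen=True)
class PTS1Result:
    """Wild-type vs mutant scores, categories, and their difference (MT-WT)."""

    wt_score: float
    mt_score: float
    wt_category: str
    mt_category: str
    score_difference: float


def is_canonical_pts1(
    tripeptide: str,
    consensus: Tuple[frozenset, frozenset, frozenset] = DEFAULT_CONSENSUS,
) -> bool:
    """Does the tripeptide match the (configurable) PTS1 consensus?"""
    if len(tripeptide) != 3:
        raise SequenceError(f"tripeptide must have 3 residues, got {tripeptide!r}")
    for aa in tripeptide:
        if aa not in AMINO_ACIDS:
            raise SequenceError(f"unsupported residue {aa!r} in {tripeptide!r}")
    return all(aa in allowed for aa, allowed in zip(tripeptide, consensus))


def pssm_score(c_terminus_12aa: str, m: Pts1Matrix) -> float:
    """Sum the matrix contributions over the 12 aligned positions.

    Sequences shorter or longer than 12 residues are rejected — there
    is no defensible padding scheme for short proteins, so callers
    must exclude them up front.
    """
    if len(c_terminus_12aa) != WINDOW_LENGTH:
        raise SequenceError(
            f"scoring window must be exactly {WINDOW_LENGTH} residues, "
            f"got {len(c_terminus_12aa)}"
        )
    total = 0.0
    for pos, aa in enumerate(c_terminus_12aa, start=1):
        if aa not in AMINO_ACIDS:
            raise SequenceError(f"unsupported residue {aa!r} at window position {pos}")
        total += m.entries[(pos, aa)]
    return total


def categorize(score: float, m: Pts1Matrix) -> str:
    """Map a score onto the three targeting categories.

    A score exactly at a threshold joins the higher category.
    """
    if score >= m.t_targeted:
        return TARGETED
    if score >= m.t_twilight:
        return TWILIGHT
    return NOT_TARGETED


def score_pair(wt_12aa: str, mt_12aa: str, m: Pts1Matrix) -> PTS1Result:
    """Score a wild-type/mutant pair; difference is MT minus WT."""
    wt = pssm_score(wt_12aa, m)
    mt = pssm_score(mt_12aa, m)
    return PTS1Result(
        wt_score=wt,
        mt_score=mt,
        wt_category=categorize(wt, m),
        mt_category=categorize(mt, m),
        score_difference=mt - wt,
    )


# ---------------------------------------------------------------------------
# Matrix file format
#
# Line 1: header — "position" followed by the 20 residue letters (any order).
# Lines 2-13: position number followed by 20 scores.
# Footer: two lines "#t_targeted<TAB>value" and "#t_twilight<TAB>value".
# Strict parse: wrong shape, duplicate positions or missing footer all fail.


def read_matrix(path: Union[str, Path], name: str = "") -> Pts1Matrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    return _parse_matrix_lines(lines, name or str(path))


def _parse_matrix_lines(lines: List[str], name: str) -> Pts1Matrix:
    if len(lines) != 1 + WINDOW_LENGTH + 2:
        raise MatrixFormatError(
            f"{name}: expected {1 + WINDOW_LENGTH + 2} non-empty lines, got {len(lines)}"
        )
    header = lines[0].split("\t")
    if header[0] != "position" or sorted(header[1:]) != sorted(AMINO_ACIDS):
        raise MatrixFormatError(f"{name}: bad header line")
    residues = header[1:]
    entries: Dict[Tuple[int, str], float] = {}
    seen_positions = set()
    for ln in lines[1 : 1 + WINDOW_LENGTH]:
        fields = ln.split("\t")
        if len(fields) != 21:
            raise MatrixFormatError(f"{name}: data row with {len(fields)} fields")
        try:
            pos = int(fields[0])
            scores = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"{name}: non-numeric matrix entry: {exc}") from exc
        if pos in seen_positions or not 1 <= pos <= WINDOW_LENGTH:
            raise MatrixFormatError(f"{name}: bad or duplicate position {pos}")
        seen_positions.add(pos)
        for aa, s in zip(residues, scores):
            entries[(pos, aa)] = s
    thresholds = {}
    for ln in lines[-2:]:
        fields = ln.split("\t")
        if len(fields) != 2 or fields[0] not in ("#t_targeted", "#t_twilight"):
            raise MatrixFormatError(f"{name}: bad threshold footer line {ln!r}")
        thresholds[fields[0]] = float(fields[1])
    if set(thresholds) != {"#t_targeted", "#t_twilight"}:
        raise MatrixFormatError(f"{name}: footer must define both thresholds")
    return Pts1Matrix(
        entries=entries,
        t_targeted=thresholds["#t_targeted"],
        t_twilight=thresholds["#t_twilight"],
        name=name,
    )


def write_matrix(m: Pts1Matrix, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
        for pos in range(1, WINDOW_LENGTH + 1):
            row = "\t".join(repr(m.entries[(pos, aa)]) for aa in AMINO_ACIDS)
            fh.write(f"{pos}\t{row}\n")
        fh.write(f"#t_targeted\t{m.t_targeted!r}\n")
        fh.write(f"#t_twilight\t{m.t_twilight!r}\n")


def zero_matrix(t_targeted: float = 1.0, t_twilight: float = 0.0) -> Pts1Matrix:
    """All-zero placeholder matrix; every sequence scores 0."""
    entries = {
        (p, aa): 0.0 for p in range(1, WINDOW_LENGTH + 1) for aa in AMINO_ACIDS
    }
    return Pts1Matrix(entries, t_targeted, t_twilight, name="zero-placeholder")


def example_matrix() -> Pts1Matrix:
    """The documented example matrix bundled with the package.

    Rewards the classical consensus residues at the last three window
    positions (with a modest credit for Asn at the penultimate
    position and Met/Val at the last) and is neutral over the nine
    upstream positions.  It is a teaching and testing device, not a
    reconstruction of any published predictor.
    """
    ref = resources.files("pts1scan.data").joinpath("example_matrix.tsv")
    with resources.as_file(ref) as path:
        return read_matrix(path, name="example")
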