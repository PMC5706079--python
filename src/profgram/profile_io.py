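"""Readers for HHblits ``.hhm`` and PSI-BLAST ASCII PSSM profiles.

Both formats describe a protein of length L as an L x 20 grid of per-position
amino-acid substitution scores.  This module parses the two text dialects into
raw records and converts them to :class:`ProfileMatrix` objects holding linear
substitution probabilities — the common currency for feature extraction.

Score conventions
-----------------
``.hhm`` match-emission scores are negated scaled log2 probabilities,
``N = -1000 * log2(p)``, so the inverse transform is ``p = 2**(-N/1000)``.
A literal ``*`` encodes probability zero and is kept as the sentinel value
:data:`SENTINEL` in the integer grid.

ASCII PSSM files store integer log-odds scores; these are mapped to (0, 1)
with the logistic transform ``1 / (1 + exp(-x))``, the standard squashing
used in the PSSM-bigram literature.  The transform is a named, swappable
strategy (see :func:`pssm_to_probability_matrix`).

Column order
------------
The ``.hhm`` emission-column order (A C D E F G H I K L M N P Q R S T V W Y)
is canonical throughout the package.  PSSM columns arrive in BLAST order
(A R N D C Q E G H I L K M F P S T W V Y) and are re-mapped to canonical at
parse time, so features computed from either origin are directly comparable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Literal

import numpy as np
from scipy.special import expit

from .exceptions import MalformedFileError, MalformedRowError

#: Canonical amino-acid column order (the .hhm emission order).
CANONICAL_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by PSI-BLAST ASCII PSSM files.
PSSM_ALPHABET: str = "ARNDCQEGHILKMFPSTWVY"

#: Sentinel stored in integer score grids for the .hhm literal ``*``
#: (probability exactly zero).  Real scores are non-negative, so -1 is safe.
SENTINEL: int = -1

# permutation such that pssm_grid[:, PSSM_TO_CANONICAL] is in canonical order
PSSM_TO_CANONICAL = np.array([PSSM_ALPHABET.index(a) for a in CANONICAL_ALPHABET])
CANONICAL_TO_PSSM = np.array([CANONICAL_ALPHABET.index(a) for a in PSSM_ALPHABET])

Origin = Literal["HMM", "PSSM"]


@dataclass
class HMMProfileRecord:
    """Raw parse of one ``.hhm`` file: residues plus the L x 20 match-emission
    score grid (integers; :data:`SENTINEL` marks ``*`` entries)."""

    sequence_id: str
    residues: str
    match_scores: np.ndarray  # (L, 20) int64, SENTINEL for '*'
    source_path: str = "<stream>"

    def __post_init__(self) -> None:
        self.match_scores = np.asarray(self.match_scores, dtype=np.int64)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise MalformedFileError(
                f"score grid must be L x 20, got {self.match_scores.shape}",
                self.source_path,
            )
        if len(self.residues) != self.match_scores.shape[0] or len(self.residues) < 1:
            raise MalformedFileError(
                f"{len(self.residues)} residues but {self.match_scores.shape[0]} score rows",
                self.source_path,
            )
        bad = (self.match_scores < 0) & (self.match_scores != SENTINEL)
        if bad.any():
            pos = int(np.argwhere(bad)[0, 0]) + 1
            raise MalformedRowError("negative non-sentinel score", self.source_path, pos)

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]


@dataclass
class PSSMRecord:
    """Raw parse of one ASCII PSSM: the first 20-column (log-odds) block,
    already re-mapped to the canonical column order."""

    sequence_id: str
    residues: str
    log_odds: np.ndarray  # (L, 20) int64, canonical column order
    source_path: str = "<stream>"

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=np.int64)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 20:
            raise MalformedFileError(
                f"log-odds grid must be L x 20, got {self.log_odds.shape}",
                self.source_path,
            )
        if len(self.residues) != self.log_odds.shape[0] or len(self.residues) < 1:
            raise MalformedFileError(
                f"{len(self.residues)} residues but {self.log_odds.shape[0]} rows",
                self.source_path,
            )

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


@dataclass
class ProfileMatrix:
    """L x 20 grid of linear substitution probabilities in canonical column
    order; the input to monogram/bigram feature extraction."""

    sequence_id: str
    values: np.ndarray  # (L, 20) float64 in [0, 1]
    origin: Origin
    column_alphabet: str = field(default=CANONICAL_ALPHABET)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got {self.values.shape}")
        if self.values.shape[0] < 1:
            raise ValueError("profile must have L >= 1 rows")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("profile entries must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _as_text(source: str | IO[str]) -> tuple[str, str]:
    """Return (text, path_label) from a path, text content, or file handle."""
    if hasattr(source, "read"):
        name = getattr(source, "name", "<stream>")
        return source.read(), str(name)
    text = str(source)
    if "\n" not in text:  # a path, not file content
        with io.open(text, "r", encoding="utf-8") as fh:
            return fh.read(), text
    return text, "<stream>"


def parse_hhm(source: str | IO[str], source_path: str | None = None) -> HMMProfileRecord:
    """Parse a ``.hhm`` file into an :class:`HMMProfileRecord`.

    ``source`` may be a filesystem path, an open text handle, or the file
    content itself.  Only the 20 match-emission scores per position are kept;
    the null model, transition fields, and insert-state lines are discarded.

    Raises
    ------
    MalformedFileError
        If the ``HMM`` tag or ``//`` terminator is missing, or the body is empty.
    MalformedRowError
        If a match-emission row does not carry 20 score fields.
    """
    text, path = _as_text(source)
    if source_path is not None:
        path = source_path
    lines = text.splitlines()

    name = ""
    hmm_line = None
    for i, line in enumerate(lines):
        tok = line.split()
        if tok[:1] == ["NAME"] and len(tok) > 1 and not name:
            name = tok[1]
        if tok[:1] == ["HMM"]:
            hmm_line = i
            break
    if hmm_line is None:
        raise MalformedFileError("missing 'HMM' tag", path, len(lines))

    residues: list[str] = []
    rows: list[list[int]] = []
    terminated = False
    # hmm_line holds the column labels; hmm_line+1 the transition labels.
    for i in range(hmm_line + 2, len(lines)):
        tok = lines[i].split()
        if not tok:
            continue
        if tok[0] == "//":
            terminated = True
            break
        # Match-emission lines start with a residue letter and 1-based position;
        # everything else (begin-state line, insert/transition lines) is skipped.
        if len(tok) >= 2 and len(tok[0]) == 1 and tok[0].isalpha() and tok[1].isdigit():
            pos = int(tok[1])
            fields = tok[2:22]
            if len(fields) < 20:
                raise MalformedRowError(
                    f"expected 20 emission scores, found {len(fields)}", path, pos
                )
            row = []
            for f in fields:
                if f == "*":
                    row.append(SENTINEL)
                elif f.isdigit():
                    row.append(int(f))
                else:
                    raise MalformedRowError(f"invalid score field {f!r}", path, pos)
            residues.append(tok[0])
            rows.append(row)
    if not terminated:
        raise MalformedFileError("missing '//' terminator", path, len(lines))
    if not rows:
        raise MalformedFileError("no match-emission rows found", path)

    return HMMProfileRecord(
        sequence_id=name or path,
        residues="".join(residues),
        match_scores=np.array(rows, dtype=np.int64),
        source_path=path,
    )


def hhm_to_probability_matrix(record: HMMProfileRecord) -> ProfileMatrix:
    """Convert ``.hhm`` scores to linear probabilities via ``p = 2**(-N/1000)``.

    Sentinel entries (the literal ``*``, i.e. ``-1000*log2(0)``) map to
    probability exactly 0.
    """
    scores = record.match_scores
    probs = np.where(
        scores == SENTINEL, 0.0, np.exp2(-scores.astype(np.float64) / 1000.0)
    )
    return ProfileMatrix(record.sequence_id, probs, origin="HMM")


def parse_pssm(source: str | IO[str], source_path: str | None = None) -> PSSMRecord:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    Keeps only the first 20-column log-odds block and re-maps its columns
    from BLAST order to the canonical alphabet.

    Raises
    ------
    MalformedFileError
        If no column-label line or no data rows are found.
    MalformedRowError
        If a data row has fewer than 22 leading tokens
        (position, residue, 20 log-odds integers).
    """
    text, path = _as_text(source)
    if source_path is not None:
        path = source_path
    lines = text.splitlines()

    label_line = None
    order = None
    for i, line in enumerate(lines):
        tok = line.split()
        if len(tok) >= 20 and all(len(t) == 1 and t.isalpha() for t in tok):
            label_line = i
            order = "".join(tok[:20])
            break
    if label_line is None:
        raise MalformedFileError("missing PSSM column-label line", path)

    perm = np.array([order.index(a) for a in CANONICAL_ALPHABET])

    residues: list[str] = []
    rows: list[list[int]] = []
    for i in range(label_line + 1, len(lines)):
        tok = lines[i].split()
        if not tok:
            break  # blank line ends the body; footer follows
        if not tok[0].lstrip("-").isdigit():
            break
        pos = int(tok[0])
        if len(tok) < 22:
            raise MalformedRowError(
                f"expected >= 22 tokens (position, residue, 20 scores), found {len(tok)}",
                path,
                pos,
            )
        try:
            row = [int(t) for t in tok[2:22]]
        except ValueError as exc:
            raise MalformedRowError(f"non-integer log-odds field: {exc}", path, pos)
        residues.append(tok[1])
        rows.append(row)
    if not rows:
        raise MalformedFileError("PSSM body is empty", path)

    grid = np.array(rows, dtype=np.int64)[:, perm]
    return PSSMRecord(
        sequence_id=path, residues="".join(residues), log_odds=grid, source_path=path
    )


def pssm_to_probability_matrix(record: PSSMRecord) -> ProfileMatrix:
    """Map PSSM log-odds x to (0, 1) with the logistic transform 1/(1+e^-x)."""
    probs = expit(record.log_odds.astype(np.float64))
    return ProfileMatrix(record.sequence_id, probs, origin="PSSM")
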