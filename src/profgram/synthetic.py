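"""Synthetic profile generator and fixture writers.

Emulates the inputs of a DNA-binding protein predictor without running
HHblits or PSI-BLAST: each instance is an L x 20 row-stochastic profile whose
rows are Dirichlet draws around a per-instance amino-acid composition.

Class signal is injected in two independent places so that both feature
families can be ablated separately:

* composition shift (monogram signal): positive instances move a fraction of
  composition mass, proportional to ``effect``, from the background toward a
  designated subset of columns — lysine/arginine-rich, mimicking the charged
  DNA-contacting surfaces of real binders;
* transition motif (bigram signal): positive instances carry ``effect``-many
  R -> K adjacent-position motifs per ten residues, sharpening specific
  bigram cells without changing the marginal composition much.

At ``effect = 0`` both mechanisms vanish and the two classes are exchangeable
in distribution.  Everything is reproducible from the config seed.

The module also writes parser-compatible ``.hhm`` and ASCII-PSSM fixture
files (synthetic stand-ins for real HHblits/PSI-BLAST output) and converts
probability profiles back to integer score records via the inverse transform
``N = round(-1000 * log2(p))`` with p = 0 mapped to ``*``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError
from .features import FeatureGroup, LabeledDataset, featurize_dataset
from .profile_io import (
    CANONICAL_ALPHABET,
    CANONICAL_TO_PSSM,
    PSSM_ALPHABET,
    SENTINEL,
    HMMProfileRecord,
    Origin,
    ProfileMatrix,
    PSSMRecord,
)

#: Background amino-acid composition (approximate natural frequencies),
#: canonical column order, normalized to sum to 1.
BACKGROUND = np.array(
    [8.3, 1.7, 5.5, 6.2, 3.9, 7.1, 2.2, 5.2, 5.8, 9.0,
     2.4, 4.4, 4.7, 3.9, 5.7, 6.9, 5.6, 6.6, 1.1, 3.2]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: Columns enriched in the positive class (K, R, N, G — basic / minor-groove
#: contacting residues typical of DNA binders).
ENRICHED_COLUMNS = tuple(CANONICAL_ALPHABET.index(a) for a in "KRNG")

#: The two-column adjacent transition motif carried by positives (R -> K).
MOTIF_PAIR = (CANONICAL_ALPHABET.index("R"), CANONICAL_ALPHABET.index("K"))

# Fraction of composition mass moved to the enriched columns at effect = 1,
# and per-instance composition variability (Dirichlet sharpness around the
# class composition).  Fixed design constants, not user dials.
_SHIFT_AT_FULL_EFFECT = 0.5
_INSTANCE_KAPPA = 60.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    effect in [0, 1] controls class separation (0 = exchangeable classes);
    concentration is the Dirichlet sharpness of each profile row around the
    instance composition (larger = crisper rows).
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 120)
    effect: float = 0.8
    concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InvalidInputError("n_pos and n_neg must be positive")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise InvalidInputError(
                f"length_range must satisfy 2 <= L_min <= L_max, got {self.length_range}"
            )
        if not 0.0 <= self.effect <= 1.0:
            raise InvalidInputError(f"effect must lie in [0, 1], got {self.effect}")
        if self.concentration <= 0:
            raise InvalidInputError("concentration must be positive")


def _positive_composition(effect: float) -> np.ndarray:
    target = np.zeros(20)
    target[list(ENRICHED_COLUMNS)] = 1.0 / len(ENRICHED_COLUMNS)
    w = _SHIFT_AT_FULL_EFFECT * effect
    return (1.0 - w) * BACKGROUND + w * target


def _one_profile(
    rng: np.random.Generator,
    L: int,
    positive: bool,
    effect: float,
    concentration: float,
    instance_id: str,
) -> ProfileMatrix:
    base = _positive_composition(effect) if positive else BACKGROUND
    comp = rng.dirichlet(_INSTANCE_KAPPA * base)
    rows = rng.dirichlet(concentration * comp, size=L)
    if positive and effect > 0:
        n_motifs = int(round(effect * L / 10))
        if n_motifs > 0:
            starts = rng.choice(L - 1, size=min(n_motifs, L - 1), replace=False)
            a, b = MOTIF_PAIR
            comp_a = 0.1 * comp.copy()
            comp_a[a] += 0.9
            comp_b = 0.1 * comp.copy()
            comp_b[b] += 0.9
            rows[starts] = rng.dirichlet(concentration * comp_a, size=len(starts))
            rows[starts + 1] = rng.dirichlet(concentration * comp_b, size=len(starts))
    return ProfileMatrix(instance_id, rows, origin="HMM")


def generate_profiles(
    config: SyntheticConfig, origin: Origin = "HMM"
) -> tuple[list[ProfileMatrix], np.ndarray]:
    """Draw labelled synthetic profiles (positives first, then negatives).

    With ``origin="PSSM"`` the probability rows are additionally quantized
    through integer log-odds and back (what parsing a written PSSM fixture
    would yield), and the matrices are tagged accordingly.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    profiles: list[ProfileMatrix] = []
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=np.int64), np.zeros(config.n_neg, dtype=np.int64)]
    )
    for i in range(config.n_pos + config.n_neg):
        positive = bool(labels[i])
        prefix = "pos" if positive else "neg"
        k = i if positive else i - config.n_pos
        L = int(rng.integers(lo, hi + 1))
        M = _one_profile(
            rng, L, positive, config.effect, config.concentration, f"{prefix}_{k:04d}"
        )
        if origin == "PSSM":
            rec = profile_to_pssm_record(M)
            from .profile_io import pssm_to_probability_matrix

            M2 = pssm_to_probability_matrix(rec)
            M = ProfileMatrix(M.sequence_id, M2.values, origin="PSSM")
        profiles.append(M)
    return profiles, labels


def generate_dataset(
    config: SyntheticConfig,
    group: FeatureGroup | str = FeatureGroup.COMBINED,
    origin: Origin = "HMM",
) -> LabeledDataset:
    """Generate profiles and featurize them in one step."""
    profiles, labels = generate_profiles(config, origin=origin)
    return featurize_dataset(profiles, labels, group)


# ---------------------------------------------------------------------------
# Score-record conversion and fixture writers
# ---------------------------------------------------------------------------


def _residues_for(values: np.ndarray) -> str:
    return "".join(CANONICAL_ALPHABET[j] for j in values.argmax(axis=1))


def profile_to_hhm_record(M: ProfileMatrix, residues: str | None = None) -> HMMProfileRecord:
    """Quantize probabilities to .hhm integer scores, N = round(-1000*log2(p));
    p = 0 maps to the ``*`` sentinel."""
    p = M.values
    with np.errstate(divide="ignore"):
        scores = np.where(
            p == 0, SENTINEL, np.rint(-1000.0 * np.log2(np.where(p == 0, 1.0, p)))
        ).astype(np.int64)
    return HMMProfileRecord(
        sequence_id=M.sequence_id,
        residues=residues or _residues_for(p),
        match_scores=scores,
    )


def profile_to_pssm_record(M: ProfileMatrix, residues: str | None = None) -> PSSMRecord:
    """Quantize probabilities to integer log-odds via the logit transform."""
    p = np.clip(M.values, 1e-9, 1.0 - 1e-9)
    log_odds = np.rint(np.log(p / (1.0 - p))).astype(np.int64)
    return PSSMRecord(
        sequence_id=M.sequence_id,
        residues=residues or _residues_for(M.values),
        log_odds=log_odds,
    )


def random_hhm_record(rng: np.random.Generator, L: int, sequence_id: str) -> HMMProfileRecord:
    """Random integer-score record for round-trip testing (some ``*`` entries)."""
    scores = rng.integers(0, 6000, size=(L, 20)).astype(np.int64)
    mask = rng.random((L, 20)) < 0.05
    scores[mask] = SENTINEL
    residues = "".join(rng.choice(list(CANONICAL_ALPHABET), size=L))
    return HMMProfileRecord(sequence_id, residues, scores)


def random_pssm_record(rng: np.random.Generator, L: int, sequence_id: str) -> PSSMRecord:
    """Random integer log-odds record (canonical column order)."""
    grid = rng.integers(-10, 13, size=(L, 20)).astype(np.int64)
    residues = "".join(rng.choice(list(CANONICAL_ALPHABET), size=L))
    return PSSMRecord(sequence_id, residues, grid)


def write_hhm_fixture(record: HMMProfileRecord, path: str | Path) -> None:
    """Write a minimal-but-valid ``.hhm`` file that parses back to ``record``."""
    path = Path(path)
    lines = [
        "HHsearch 1.5",
        f"NAME  {record.sequence_id}",
        f"LENG  {record.length} match states, {record.length} columns in multiple alignment",
        "SEQ",
        f">{record.sequence_id}",
        record.residues,
        "#",
        "HMM    " + "\t".join(CANONICAL_ALPHABET),
        "       " + "\t".join(
            ["M->M", "M->I", "M->D", "I->M", "I->I", "D->M", "D->D", "Neff", "Neff_I", "Neff_D"]
        ),
        "       0\t*\t*\t*\t*\t*\t*\t*\t*\t*",
    ]
    for i in range(record.length):
        fields = [
            "*" if s == SENTINEL else str(int(s)) for s in record.match_scores[i]
        ]
        lines.append(f"{record.residues[i]} {i + 1}\t" + "\t".join(fields) + f"\t{i + 1}")
        lines.append("       0\t*\t*\t*\t*\t*\t*\t1000\t0\t0")
        lines.append("")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")


def write_pssm_fixture(record: PSSMRecord, path: str | Path) -> None:
    """Write an ASCII PSSM (``-out_ascii_pssm`` dialect) that parses back to
    ``record``.  Columns are emitted in BLAST order; the percentage block is
    synthetic zeros."""
    path = Path(path)
    labels = "  ".join(PSSM_ALPHABET)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts",
        "            " + labels + "   " + labels,
    ]
    for i in range(record.length):
        row = record.log_odds[i][CANONICAL_TO_PSSM]
        scores = " ".join(f"{int(v):3d}" for v in row)
        pcts = " ".join("  0" for _ in range(20))
        lines.append(f"{i + 1:5d} {record.residues[i]}  {scores}  {pcts}  0.00 0.00")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1000     0.3000",
        "",
    ]
    path.write_text("\n".join(lines) + "\n")


def write_fixture_directory(
    config: SyntheticConfig, out_dir: str | Path, origin: Origin = "HMM"
) -> tuple[Path, Path]:
    """Simulate a dataset and write per-instance fixture files plus a label
    table (instance_id <tab> label).  Returns (profile_dir, labels_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles, labels = generate_profiles(config, origin=origin)
    ext = "hhm" if origin == "HMM" else "pssm"
    for M in profiles:
        target = out_dir / f"{M.sequence_id}.{ext}"
        if origin == "HMM":
            write_hhm_fixture(profile_to_hhm_record(M), target)
        else:
            write_pssm_fixture(profile_to_pssm_record(M), target)
    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("instance_id\tlabel\n")
        for M, y in zip(profiles, labels):
            fh.write(f"{M.sequence_id}\t{int(y)}\n")
    return out_dir, labels_path
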