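"""Position weight matrix handling.

PWMs (per-position nucleotide probability matrices, e.g. cisBP exports in
MEME minimal format) are the fixed prior knowledge of the model: they become
the convolution kernels of the first layer and their information content is
used when interpreting the learned pooling parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

ALPHABET = "ACGT"
_ROW_TOL = 1e-6

__all__ = [
    "PWM",
    "MotifLibrary",
    "KernelBank",
    "SimilarityMatrix",
    "read_meme",
    "write_meme",
    "read_tomtom",
    "to_kernel_bank",
    "information_content",
    "motif_similarity_matrix",
    "pwm_similarity",
]


class MotifParseError(ValueError):
    """Raised when a motif file cannot be interpreted."""


@dataclass(frozen=True)
class PWM:
    """A named probability matrix of shape (width, 4) in A,C,G,T order."""

    name: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be width x 4")
        if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
            raise ValueError(f"PWM {self.name!r}: entries outside [0, 1]")
        rowsum = m.sum(axis=1)
        if np.any(rowsum <= 0):
            raise ValueError(f"PWM {self.name!r}: a row sums to zero")
        m = np.clip(m, 0.0, None) / rowsum[:, None]
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        # reversing both axes complements because ACGT order pairs A<->T, C<->G
        return PWM(self.name, self.matrix[::-1, ::-1].copy())


@dataclass
class MotifLibrary:
    """An ordered collection of PWMs; list order defines the motif index."""

    motifs: list[PWM]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        names = [p.name for p in self.motifs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise MotifParseError(f"duplicate motif names: {dup}")
        self.background = np.asarray(self.background, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.motifs[self.index(key)]
        return self.motifs[key]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.motifs]

    @property
    def widths(self) -> np.ndarray:
        return np.array([p.width for p in self.motifs])

    @property
    def max_width(self) -> int:
        return int(self.widths.max())

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"motif {name!r} not in library") from None


@dataclass
class KernelBank:
    """Log-odds convolution kernels, one per motif, right-padded to a
    common width with exact zeros (score-neutral under log-odds scoring)."""

    weights: np.ndarray  # (m, 4, max_width)
    valid_width: np.ndarray  # (m,)
    background: np.ndarray  # (4,)

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def max_width(self) -> int:
        return self.weights.shape[2]

    def max_scores(self) -> np.ndarray:
        """Best attainable match score per motif."""
        return self.weights.max(axis=1).sum(axis=1)

    def mean_scores(self) -> np.ndarray:
        """Expected score per motif under the background composition."""
        return (self.weights * self.background[None, :, None]).sum(axis=(1, 2))


# --------------------------------------------------------------------- I/O
def read_meme(path) -> MotifLibrary:
    """Read a MEME minimal-format motif file into a :class:`MotifLibrary`.

    Rows are renormalized to sum to one; file order is preserved.
    """
    try:
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
    except Exception as exc:  # biopython raises bare ValueError on bad blocks
        raise MotifParseError(f"{path}: malformed MEME file: {exc}") from exc
    if len(parsed) == 0:
        raise MotifParseError(f"{path}: no motifs found")
    pwms = []
    for mot in parsed:
        letters = "".join(sorted(mot.alphabet))
        if letters != ALPHABET:
            raise MotifParseError(
                f"{path}: motif {mot.name!r} uses unsupported alphabet {mot.alphabet!r}"
            )
        mat = np.column_stack([np.asarray(mot.counts[b], float) for b in ALPHABET])
        rowsum = mat.sum(axis=1, keepdims=True)  # parser rescales by nsites
        if np.any(rowsum <= 0):
            raise MotifParseError(f"{path}: motif {mot.name!r} has an empty row")
        pwms.append(PWM(mot.name, mat / rowsum))
    bg = parsed[0].background
    background = np.array([bg[b] for b in ALPHABET]) if bg else np.full(4, 0.25)
    return MotifLibrary(pwms, background=background)


def write_meme(lib: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, lib.background)) + "\n\n"
        )
        for pwm in lib:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_tomtom(path) -> dict[tuple[str, str], float]:
    """Read a TOMTOM tabular output into a {(query, target): E-value} map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    try:
        q, t, e = cols["query_id"], cols["target_id"], cols["e-value"]
    except KeyError as exc:
        raise MotifParseError(f"{path}: missing TOMTOM column {exc}") from exc
    return {
        (str(r[q]), str(r[t])): float(r[e]) for _, r in df.iterrows()
    }


# --------------------------------------------------------------- transforms
def to_kernel_bank(
    lib: MotifLibrary,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> KernelBank:
    """Convert a library to log-odds kernels.

    weight[i, n, j] = log((p_ij(n) + pc * bg(n)) / ((1 + pc) * bg(n))) for
    positions inside the motif; positions beyond a motif's width are exactly
    zero so every kernel shares the padded width without affecting scores.
    """
    bg = np.asarray(
        lib.background if background is None else background, dtype=np.float64
    )
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 strictly positive frequencies")
    bg = bg / bg.sum()
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    m, W = len(lib), lib.max_width
    weights = np.zeros((m, 4, W))
    for i, pwm in enumerate(lib):
        p = pwm.matrix.T  # (4, width)
        weights[i, :, : pwm.width] = np.log(
            (p + pseudocount * bg[:, None]) / ((1 + pseudocount) * bg[:, None])
        )
    return KernelBank(weights=weights, valid_width=lib.widths.copy(), background=bg)


def information_content(
    pwm: PWM, background: np.ndarray | None = None
) -> float:
    """Total information content in bits: sum_j sum_n p log2(p / bg)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
    return float(terms.sum())


# --------------------------------------------------------------- similarity
def pwm_similarity(a: np.ndarray, b: np.ndarray, min_overlap: int = 4) -> float:
    """Best ungapped-alignment Pearson correlation between two matrices.

    Scans all offsets and both orientations of ``b`` (reverse complement =
    both axes reversed in ACGT order); overlaps shorter than ``min_overlap``
    columns (or the shorter motif, if shorter) are skipped so that a single
    coincidental column cannot claim a perfect match.
    """
    a = np.asarray(a, float)
    best = -1.0
    need = min(min_overlap, a.shape[0], np.asarray(b).shape[0])
    for mat in (np.asarray(b, float), np.asarray(b, float)[::-1, ::-1]):
        wa, wb = a.shape[0], mat.shape[0]
        for off in range(-(wb - 1), wa):
            lo_a, hi_a = max(0, off), min(wa, off + wb)
            if hi_a - lo_a < need:
                continue
            xa = a[lo_a:hi_a].ravel()
            xb = mat[lo_a - off : hi_a - off].ravel()
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            if r > best:
                best = r
    return best


@dataclass
class SimilarityMatrix:
    """Pairwise motif similarity with an explicit orientation convention.

    ``higher_is_similar`` is True for the built-in correlation fallback and
    False for external log10(E-value) scores, where lower means more similar.
    """

    values: np.ndarray  # (m, m)
    names: list[str]
    higher_is_similar: bool
    source: str  # "fallback" or "external"

    def oriented(self) -> np.ndarray:
        """Values on a scale where larger always means more similar."""
        return self.values if self.higher_is_similar else -self.values


def motif_similarity_matrix(
    lib: MotifLibrary,
    external_scores: dict[tuple[str, str], float] | None = None,
    min_overlap: int = 4,
) -> SimilarityMatrix:
    """Pairwise similarity for all motifs in library order.

    With ``external_scores`` (query, target) -> E-value pairs the entries
    are log10(E-value) (lower = more similar); missing pairs get log10 of
    the most dissimilar provided E-value. Otherwise a built-in fallback is
    used: best ungapped-alignment Pearson correlation over all offsets and
    both orientations (higher = more similar), flagged as non-external.
    """
    m = len(lib)
    names = lib.names
    if external_scores is not None:
        known = set(names)
        for q, t in external_scores:
            if q not in known or t not in known:
                raise KeyError(f"external score references unknown motif ({q}, {t})")
        worst = math.log10(max(external_scores.values())) if external_scores else 0.0
        vals = np.full((m, m), worst)
        idx = {n: i for i, n in enumerate(names)}
        for (q, t), e in external_scores.items():
            vals[idx[q], idx[t]] = math.log10(e)
        return SimilarityMatrix(vals, names, higher_is_similar=False, source="external")

    vals = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            s = pwm_similarity(
                lib.motifs[i].matrix, lib.motifs[j].matrix, min_overlap=min_overlap
            )
            vals[i, j] = vals[j, i] = s
    return SimilarityMatrix(vals, names, higher_is_similar=True, source="fallback")
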