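"""Synthetic sequence -> activity benchmarks with planted ground truth.

Background sequences are i.i.d. uniform ACGT; chosen motifs are planted by
sampling bases from their PWM at non-overlapping random offsets (on a random
strand), so match scores are graded rather than binary and the calibration
layer is genuinely exercised. Activity is a known function of the planted
signals plus Gaussian noise, where each motif contributes either through
mere presence ("max" mechanism) or through its insertion count ("count"
mechanism), optionally gated by another motif's presence — mirroring the
aggregation and interaction mechanisms the model can express. Every
insertion is recorded, so tests can verify sequence content against the log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import ActivityMatrix, EncodedBatch, encode_sequences
from .motifs import PWM, MotifLibrary, motif_similarity_matrix

__all__ = ["GroundTruth", "random_library", "generate", "recovery_score", "write_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass
class GroundTruth:
    """Known effect structure used to synthesize activities.

    effects:      (c, m) signed effect sizes aligned to library order
    mechanism:    per-motif "max" (presence indicator) or "count"
    interactions: (gater, gated, strength) triples; each adds
                  strength * presence(gater) * signal(gated) to every output
    """

    effects: np.ndarray
    mechanism: dict[str, str] = field(default_factory=dict)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def planted_motifs(self, lib: MotifLibrary) -> list[int]:
        """Indices of motifs that are inserted into sequences: any motif
        with a nonzero effect or participating in an interaction."""
        idx = set(np.flatnonzero(np.any(self.effects != 0, axis=0)))
        for gater, gated, _ in self.interactions:
            idx.add(lib.index(gater))
            idx.add(lib.index(gated))
        return sorted(idx)


def random_library(
    m: int,
    width: int = 8,
    seed: int = 0,
    concentration: float = 0.2,
    max_similarity: float | None = None,
) -> MotifLibrary:
    """Random sharp PWMs (per-column Dirichlet draws); low concentration
    gives high-information motifs resembling real TF binding preferences.

    With ``max_similarity`` set, each motif is rejection-sampled until its
    ungapped-correlation similarity to every earlier motif stays below the
    cap, yielding a mutually distinguishable library (useful when planted
    effects must be attributable to a single motif).
    """
    from .motifs import pwm_similarity

    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    for i in range(m):
        for _try in range(500):
            mat = rng.dirichlet(np.full(4, concentration), size=width)
            if max_similarity is None or all(
                pwm_similarity(mat, p.matrix) < max_similarity for p in pwms
            ):
                break
        else:
            raise RuntimeError(
                f"could not draw motif {i} below similarity {max_similarity}"
            )
        pwms.append(PWM(f"motif{i:03d}", mat))
    return MotifLibrary(pwms)


def perturbed_copy(pwm: PWM, name: str, amount: float = 0.15) -> PWM:
    """A near-duplicate of ``pwm``: columns mixed with the uniform
    distribution. The copy keeps the consensus (high pairwise similarity)
    but its match scores are not exactly collinear with the original's, the
    situation real motif databases create with same-family PWMs."""
    if not 0 < amount < 1:
        raise ValueError("amount must lie in (0, 1)")
    mat = (1 - amount) * pwm.matrix + amount * 0.25
    return PWM(name, mat)


def _sample_site(pwm: PWM, rng) -> str:
    rows = [rng.choice(4, p=row) for row in pwm.matrix]
    return "".join("ACGT"[i] for i in rows)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate(
    lib: MotifLibrary,
    truth: GroundTruth,
    n: int,
    L: int = 200,
    c: int | None = None,
    max_count: int = 3,
    plant_prob: float = 0.5,
) -> tuple[EncodedBatch, ActivityMatrix, list[dict]]:
    """Generate n regions of length L with planted motifs and activities.

    Per region and planted motif, the insertion count is 0 with probability
    ``1 - plant_prob`` and otherwise uniform on {1, ..., max_count}.
    Activity for output o is

        sum_i effects[o, i] * signal_i + sum_(g,t,s) s * presence_g * signal_t
        + Gaussian(0, noise_sd)

    with signal_i the presence indicator ("max") or the count ("count").
    Returns the encoded batch, the activity matrix, and a planting log with
    one record per insertion (region, motif, offset, strand, bases).
    """
    if n < 1:
        raise ValueError("need at least one region")
    effects = np.asarray(truth.effects, dtype=float)
    c_out = effects.shape[0] if c is None else c
    if effects.shape != (c_out, len(lib)):
        raise ValueError(f"effects must have shape ({c_out}, {len(lib)})")
    planted = truth.planted_motifs(lib)
    for i in planted:
        if lib.motifs[i].width > L:
            raise ValueError(f"motif {lib.names[i]!r} wider than region length {L}")
    rng = np.random.default_rng(truth.seed)

    seqs: dict[str, str] = {}
    log: list[dict] = []
    counts = np.zeros((n, len(lib)), dtype=int)
    for r in range(n):
        rid = f"region{r:05d}"
        chars = list(_BASES[rng.integers(0, 4, size=L)])
        occupied: list[tuple[int, int]] = []
        for i in planted:
            if rng.random() >= plant_prob:
                continue
            k = int(rng.integers(1, max_count + 1))
            pwm = lib.motifs[i]
            for _ in range(k):
                placed = False
                for _try in range(200):
                    off = int(rng.integers(0, L - pwm.width + 1))
                    span = (off, off + pwm.width)
                    if all(span[1] <= s or span[0] >= e for s, e in occupied):
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        f"could not place motif {pwm.name!r} without overlap in "
                        f"region {rid}; lower max_count or enlarge L"
                    )
                site = _sample_site(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                ins = site if strand == "+" else _revcomp(site)
                chars[span[0] : span[1]] = list(ins)
                occupied.append(span)
                counts[r, i] += 1
                log.append(
                    {"region": rid, "motif": pwm.name, "offset": span[0],
                     "strand": strand, "bases": ins}
                )
        seqs[rid] = "".join(chars)

    signal = counts.astype(float)
    for i in planted:
        if truth.mechanism.get(lib.names[i], "max") == "max":
            signal[:, i] = (counts[:, i] > 0).astype(float)
    activity = signal @ effects.T
    for gater, gated, strength in truth.interactions:
        gi, ti = lib.index(gater), lib.index(gated)
        term = strength * (counts[:, gi] > 0) * signal[:, ti]
        activity += term[:, None]
    if truth.noise_sd > 0:
        activity += rng.normal(0.0, truth.noise_sd, size=activity.shape)

    batch = encode_sequences(seqs, L=L)
    act = ActivityMatrix(
        activity, batch.region_ids, [f"output{j}" for j in range(c_out)], "raw"
    )
    return batch, act, log


def recovery_score(
    coef: np.ndarray,
    truth: GroundTruth,
    lib: MotifLibrary,
    k: int,
    similarity_threshold: float = 0.8,
) -> tuple[np.ndarray, float]:
    """How well the final-layer coefficients recover the planted effects.

    For each output, the top-k motifs by |coefficient| are checked against
    the motifs planted with nonzero effect for that output. A selected
    motif whose ungapped-correlation similarity to a planted motif exceeds
    ``similarity_threshold`` is collapsed into that planted motif (database
    redundancy should not count as an error). Returns per-output
    precision@k and the sign agreement rate over recovered planted motifs.
    """
    coef = np.asarray(coef, dtype=float)
    effects = np.asarray(truth.effects, dtype=float)
    c, m = coef.shape
    if k > m:
        raise ValueError(f"k={k} exceeds motif count {m}")
    sim = motif_similarity_matrix(lib).values
    # map every motif to the planted motif it duplicates, if any
    planted_any = sorted(set(np.flatnonzero(np.any(effects != 0, axis=0))))
    collapse = {}
    for j in range(m):
        if j in planted_any:
            collapse[j] = j
            continue
        if planted_any:
            sims = [sim[j, p] for p in planted_any]
            best = int(np.argmax(sims))
            if sims[best] > similarity_threshold:
                collapse[j] = planted_any[best]

    precision = np.zeros(c)
    agree, recovered = 0, 0
    degenerate = not np.any(coef != 0)
    for out in range(c):
        targets = set(np.flatnonzero(effects[out] != 0))
        order = np.argsort(-np.abs(coef[out]), kind="stable")[:k]
        hits = 0
        seen: set[int] = set()
        for j in order:
            mapped = collapse.get(int(j))
            if mapped is not None and mapped in targets and mapped not in seen:
                hits += 1
                seen.add(mapped)
                recovered += 1
                if np.sign(coef[out, j]) == np.sign(effects[out, mapped]):
                    agree += 1
        precision[out] = 0.0 if degenerate else hits / k
    sign_rate = agree / recovered if recovered else 0.0
    return precision, sign_rate


def write_fixture(outdir, batch: EncodedBatch, act: ActivityMatrix,
                  log: list[dict], lib: MotifLibrary, truth: GroundTruth) -> None:
    """Write a generated dataset as FASTA + TSV + MEME + JSON so it can be
    fed back through the command-line interface."""
    from pathlib import Path

    from .data import decode_sequence, write_activity_tsv
    from .motifs import write_meme

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "sequences.fa", "w") as fh:
        for rid, row in zip(batch.region_ids, batch.onehot):
            fh.write(f">{rid}\n{decode_sequence(row)}\n")
    write_activity_tsv(act, out / "activity.tsv")
    write_meme(lib, out / "motifs.meme")
    payload = {
        "effects": np.asarray(truth.effects).tolist(),
        "mechanism": truth.mechanism,
        "interactions": [list(t) for t in truth.interactions],
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "motif_names": lib.names,
        "planting_log": log,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
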