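"""Synthetic PSSM profile generator.

Real adaptor-protein PSSM datasets pair extreme length variability (the
shortest profile has 18 positions, the longest over 20,000) with a roughly
1:9 positive:negative imbalance. The generator reproduces that statistical
shape at desk scale: lengths drawn log-uniformly, integer log-odds scores
from rounded clipped Gaussian noise, and — in positive profiles — a short
motif window in which a fixed subset of residue columns is shifted upward,
mimicking the conserved columns that distinguish a protein family. Because
the classifier ends in global average pooling, the discriminative signal is
carried by column statistics, which this construction guarantees survives
pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profiles import (
    RESIDUE_ORDER,
    LabeledDataset,
    PSSMProfile,
    write_manifest,
    write_pssm_file,
)

#: Residue columns boosted in positive-class motifs (indices into RESIDUE_ORDER).
MOTIF_COLUMNS = (2, 5, 9, 13, 17)  # N, Q, I, F, Y


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Defaults emulate the study conditions: 200 adaptors vs 1800 non-adaptors
    (1:9 imbalance), lengths 18–500 drawn log-uniformly, integer scores in
    the usual PSI-BLAST log-odds range.
    """

    n_pos: int = 200
    n_neg: int = 1800
    min_len: int = 18
    max_len: int = 500
    motif_len: int = 9
    motif_gain: float = 6.0
    noise_sd: float = 2.0
    score_low: int = -16
    score_high: int = 13
    seed: int = 42

    def __post_init__(self) -> None:
        if self.min_len < 8:
            raise ValueError("min_len must be >= 8 (three halvings must leave >= 1)")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg < 1:
            raise ValueError("need n_pos >= 0, n_neg >= 0 and at least one profile")
        if self.motif_len < 1 or self.motif_len > self.min_len:
            raise ValueError("motif_len must be in [1, min_len]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.score_low >= self.score_high:
            raise ValueError("score_low must be < score_high")


def sample_profile(
    config: GeneratorConfig,
    label: int,
    rng: np.random.Generator,
    id: str = "",
) -> PSSMProfile:
    """Draw one synthetic profile of the given class.

    Length is log-uniform on [min_len, max_len]; background scores are
    rounded Gaussian(0, noise_sd) clipped to [score_low, score_high]. For a
    positive profile, ``motif_gain`` is added to the :data:`MOTIF_COLUMNS`
    over ``motif_len`` consecutive positions at a random offset before
    rounding and clipping. Residues are uniform over the 20-letter alphabet.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    lo, hi = np.log(config.min_len), np.log(config.max_len)
    length = int(np.floor(np.exp(rng.uniform(lo, hi))))
    length = min(max(length, config.min_len), config.max_len)

    scores = rng.normal(0.0, config.noise_sd, size=(length, 20))
    if label == 1:
        offset = int(rng.integers(0, length - config.motif_len + 1))
        window = slice(offset, offset + config.motif_len)
        scores[window, list(MOTIF_COLUMNS)] += config.motif_gain
    scores = np.clip(np.rint(scores), config.score_low, config.score_high)

    residues = "".join(
        RESIDUE_ORDER[i] for i in rng.integers(0, 20, size=length)
    )
    return PSSMProfile(id=id, residues=residues, scores=scores, label=label)


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate the full labelled cohort, shuffled by the seeded stream.

    Ids are ``pos_0001`` … / ``neg_0001`` …; two runs with the same config
    produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    profiles = [
        sample_profile(config, 1, rng, id=f"pos_{i + 1:04d}")
        for i in range(config.n_pos)
    ] + [
        sample_profile(config, 0, rng, id=f"neg_{i + 1:04d}")
        for i in range(config.n_neg)
    ]
    order = rng.permutation(len(profiles))
    return LabeledDataset([profiles[i] for i in order], name="synthetic")


def materialize_dataset(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """Write a dataset to disk as PSSM files plus a ``manifest.csv``.

    Returns the manifest path. The directory layout matches what real
    PSI-BLAST output would look like: one ASCII PSSM per protein.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for prof in dataset:
        fname = f"{prof.id}.pssm"
        write_pssm_file(prof, out_dir / fname)
        rows.append((prof.id, fname, prof.label))
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
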