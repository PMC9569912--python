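"""Desk-scale synthetic corpora and affinity datasets with a planted signal.

The generator emulates the shape of public DTA benchmarks — a sparse
drug × target interaction grid over SMILES-like and protein-like strings —
while planting a *recoverable* affinity signal: each of ``n_motifs``
drug-motif/target-motif pairs contributes an additive effect a_k to the
affinity only when the drug string contains motif k AND the target string
contains its partner motif.  The signal is therefore multiplicative in
drug and target membership, so neither a drug-only nor a target-only model
can fit it exactly; a model must represent the interaction.

Affinities live on a pKd-like scale (baseline ≈ 5, effects of order 1),
with optional additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DTDataset

__all__ = [
    "AMINO_ACIDS",
    "SMILES_ALPHABET",
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_dt_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SMILES_ALPHABET = "CNOSPclnos()=#123"


@dataclass(frozen=True)
class SynthConfig:
    """Shape and signal parameters of one synthetic dataset."""

    n_drugs: int = 50
    n_targets: int = 30
    density: float = 0.25
    drug_len_range: tuple[int, int] = (16, 48)
    target_len_range: tuple[int, int] = (50, 150)
    n_motifs: int = 4
    motif_prob: float = 0.5  # per-entity carriage probability of each motif
    effect_range: tuple[float, float] = (0.8, 2.0)
    baseline: float = 5.0
    noise_sd: float = 0.1
    degree_bias: str = "uniform"  # "uniform" | "power"
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 1 or self.n_targets < 1:
            raise ValueError("n_drugs and n_targets must be positive")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.density * self.n_drugs * self.n_targets < 1:
            raise ValueError("density infeasible: fewer than one pair")
        for lo, hi in (self.drug_len_range, self.target_len_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be non-empty and positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.degree_bias not in ("uniform", "power"):
            raise ValueError("degree_bias must be 'uniform' or 'power'")


@dataclass
class GroundTruth:
    """The planted parameters, for signal-recovery tests."""

    drug_motifs: list[str]
    target_motifs: list[str]
    effects: np.ndarray  # a_k, length n_motifs
    baseline: float
    clean_affinity: dict[tuple[str, str], float] = field(default_factory=dict)


def generate_corpus(
    n: int, alphabet: str = AMINO_ACIDS, len_range: tuple[int, int] = (50, 200),
    seed: int = 0,
) -> list[str]:
    """n i.i.d. uniform random strings with lengths in ``len_range``."""
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    out = []
    for _ in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        out.append("".join(rng.choice(letters, size=length)))
    return out


def _random_string(rng: np.random.Generator, alphabet: str, len_range) -> str:
    length = int(rng.integers(len_range[0], len_range[1] + 1))
    return "".join(rng.choice(list(alphabet), size=length))


def _plant_motifs(
    rng: np.random.Generator,
    base: str,
    motifs: list[str],
    carry: np.ndarray,
) -> str:
    s = base
    for motif, has in zip(motifs, carry):
        if has:
            pos = int(rng.integers(0, len(s) + 1))
            s = s[:pos] + motif + s[pos:]
    return s


def generate_dt_dataset(cfg: SynthConfig) -> tuple[DTDataset, GroundTruth]:
    """Generate a dataset plus the planted parameters behind its labels.

    Motif membership used for the affinity is evaluated on the *final*
    strings by substring search, so a motif that arises by chance in the
    random background still counts toward the label — labels are always an
    exact function of the emitted sequences (plus noise).
    """
    rng = np.random.default_rng(cfg.seed)
    drug_motifs = [_random_string(rng, SMILES_ALPHABET, (4, 4)) for _ in range(cfg.n_motifs)]
    target_motifs = [_random_string(rng, AMINO_ACIDS, (5, 5)) for _ in range(cfg.n_motifs)]
    effects = rng.uniform(*cfg.effect_range, size=cfg.n_motifs)

    def build_entities(n, prefix, alphabet, len_range, motifs):
        table = {}
        for i in range(n):
            carry = rng.random(cfg.n_motifs) < cfg.motif_prob
            base = _random_string(rng, alphabet, len_range)
            table[f"{prefix}{i}"] = _plant_motifs(rng, base, motifs, carry)
        return table

    drugs = build_entities(cfg.n_drugs, "D", SMILES_ALPHABET, cfg.drug_len_range, drug_motifs)
    targets = build_entities(
        cfg.n_targets, "T", AMINO_ACIDS, cfg.target_len_range, target_motifs
    )

    n_cells = cfg.n_drugs * cfg.n_targets
    n_pairs = max(1, int(round(cfg.density * n_cells)))
    if cfg.degree_bias == "uniform":
        chosen = rng.choice(n_cells, size=n_pairs, replace=False)
    else:
        # power-law drug degrees: popular compounds dominate, as in screens
        drug_w = 1.0 / np.arange(1, cfg.n_drugs + 1)
        cell_w = np.repeat(drug_w, cfg.n_targets)
        cell_w /= cell_w.sum()
        chosen = rng.choice(n_cells, size=n_pairs, replace=False, p=cell_w)

    truth = GroundTruth(drug_motifs, target_motifs, effects, cfg.baseline)
    drug_ids = list(drugs)
    target_ids = list(targets)
    drug_member = {
        d: np.array([m in s for m in drug_motifs]) for d, s in drugs.items()
    }
    target_member = {
        t: np.array([m in s for m in target_motifs]) for t, s in targets.items()
    }
    pairs = []
    for cell in sorted(int(c) for c in chosen):
        d = drug_ids[cell // cfg.n_targets]
        t = target_ids[cell % cfg.n_targets]
        clean = cfg.baseline + float(
            np.sum(effects * drug_member[d] * target_member[t])
        )
        truth.clean_affinity[(d, t)] = clean
        y = clean + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
        pairs.append((d, t, float(y)))
    return DTDataset(drugs, targets, pairs), truth
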