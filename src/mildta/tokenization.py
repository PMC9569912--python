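"""Data-driven subword tokenization of SMILES and protein sequences.

Implements unigram language-model tokenization: a vocabulary of substrings
("pieces") with log-probabilities is learned from a corpus by EM over the
segmentation lattice followed by pruning, and sequences are segmented with
the maximum-likelihood (Viterbi) decomposition.  Multi-residue pieces
compress low-entropy regions, shortening the encoded sequences that feed
the transformer encoders.

Every single character observed in the training corpus is always retained
in the vocabulary, so any string over the training alphabet is segmentable.
Characters never seen in training map to the unknown id.

Special ids are fixed: pad = 0, unk = 1; learned pieces occupy ids ≥ 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PAD_ID",
    "UNK_ID",
    "TokenSequence",
    "UnigramTokenizer",
    "train_unigram_tokenizer",
    "encode",
]

PAD_ID = 0
UNK_ID = 1
_FORMAT = "mildta-unigram"
_VERSION = 1
_UNK_PENALTY = 10.0  # added below the worst piece score for unknown chars


@dataclass(frozen=True)
class TokenSequence:
    """A fixed-length padded encoding of one sequence."""

    ids: np.ndarray  # int64, length max_len
    mask: np.ndarray  # bool, length max_len; True = real token
    original_length: int  # token count before truncation

    def __post_init__(self):
        assert self.ids.shape == self.mask.shape


def _logsumexp2(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = max(a, b)
    return m + np.log(np.exp(a - m) + np.exp(b - m))


class UnigramTokenizer(TransformerMixin, BaseEstimator):
    """Unigram-LM subword tokenizer with a scikit-learn transformer API.

    Parameters
    ----------
    vocab_size : int
        Number of learned pieces (excluding the pad and unk specials).  Must
        be at least the number of distinct characters in the corpus; if the
        corpus admits fewer distinct substrings than requested, the fitted
        vocabulary is the maximum achievable size.
    max_len : int
        Token length to which :meth:`transform` pads/truncates.
    max_token_len : int
        Longest candidate substring considered during training.
    em_iters : int
        EM sweeps per refinement round.
    prune_frac : float
        Fraction of prunable (multi-character) pieces dropped per round.
    character_level : bool
        If True, skip subword learning and use the identity (single
        character) vocabulary — the "atom-level view".
    seed : int
        Reserved for API symmetry; training itself is deterministic in the
        corpus and the parameters.
    """

    def __init__(
        self,
        vocab_size: int = 100,
        max_len: int = 128,
        max_token_len: int = 8,
        em_iters: int = 4,
        prune_frac: float = 0.25,
        character_level: bool = False,
        seed: int = 0,
    ):
        self.vocab_size = vocab_size
        self.max_len = max_len
        self.max_token_len = max_token_len
        self.em_iters = em_iters
        self.prune_frac = prune_frac
        self.character_level = character_level
        self.seed = seed

    # -- training -------------------------------------------------------------
    def fit(self, X, y=None):
        corpus = [s for s in X]
        if not corpus or all(len(s) == 0 for s in corpus):
            raise ValueError("corpus must contain at least one non-empty string")
        counts: dict[str, int] = {}
        for s in corpus:
            counts[s] = counts.get(s, 0) + 1
        alphabet = sorted({c for s in corpus for c in s})

        if self.character_level:
            logp = np.log(1.0 / len(alphabet))
            self._finalize({c: logp for c in alphabet}, alphabet)
            return self

        if self.vocab_size < len(alphabet):
            raise ValueError(
                f"vocab_size={self.vocab_size} is below the number of distinct "
                f"characters; minimum feasible size is {len(alphabet)}"
            )

        piece_counts = self._seed_pieces(counts, alphabet)
        probs = self._normalize(piece_counts)
        singles = set(alphabet)
        # alternate EM and pruning until the vocabulary reaches the target
        while True:
            for _ in range(self.em_iters):
                expected = self._e_step(counts, probs)
                probs = self._m_step(expected, probs, singles)
            n_over = len(probs) - self.vocab_size
            if n_over <= 0:
                break
            prunable = sorted(
                (t for t in probs if len(t) > 1),
                key=lambda t: (expected.get(t, 0.0), t),
            )
            batch = max(1, int(np.ceil(len(prunable) * self.prune_frac)))
            n_drop = min(n_over, batch, len(prunable))
            for t in prunable[:n_drop]:
                del probs[t]
            # renormalize in log space to survive very small probabilities
            lps = np.array(list(probs.values()))
            log_total = float(np.logaddexp.reduce(lps))
            probs = {t: lp - log_total for t, lp in probs.items()}
        self._finalize(probs, alphabet)
        return self

    def _seed_pieces(self, counts: dict[str, int], alphabet: list[str]) -> dict[str, float]:
        cand: dict[str, float] = {}
        for s, c in counts.items():
            for i in range(len(s)):
                for L in range(1, min(self.max_token_len, len(s) - i) + 1):
                    sub = s[i : i + L]
                    cand[sub] = cand.get(sub, 0.0) + c
        singles = {t: cand[t] for t in alphabet}
        multi = {t: v for t, v in cand.items() if len(t) > 1}
        # keep a bounded candidate pool, scored by frequency × length
        cap = max(8 * self.vocab_size, 256)
        keep = sorted(multi, key=lambda t: (-multi[t] * len(t), t))[:cap]
        out = dict(singles)
        for t in keep:
            out[t] = multi[t] * len(t)
        return out

    @staticmethod
    def _normalize(weights: dict[str, float]) -> dict[str, float]:
        total = sum(weights.values())
        log_total = float(np.log(total))
        return {
            t: float(np.log(w)) - log_total for t, w in weights.items() if w > 0
        }

    def _e_step(self, counts: dict[str, int], probs: dict[str, float]) -> dict[str, float]:
        expected: dict[str, float] = {}
        maxlen = max(len(t) for t in probs)
        for s, c in counts.items():
            n = len(s)
            alpha = np.full(n + 1, -np.inf)
            alpha[0] = 0.0
            spans = []  # (j, i, token, logp)
            for i in range(1, n + 1):
                for L in range(1, min(maxlen, i) + 1):
                    tok = s[i - L : i]
                    lp = probs.get(tok)
                    if lp is None:
                        continue
                    spans.append((i - L, i, tok, lp))
                    alpha[i] = _logsumexp2(alpha[i], alpha[i - L] + lp)
            if alpha[n] == -np.inf:
                continue  # unsegmentable (cannot happen with singles present)
            beta = np.full(n + 1, -np.inf)
            beta[n] = 0.0
            for j, i, tok, lp in reversed(spans):
                beta[j] = _logsumexp2(beta[j], lp + beta[i])
            for j, i, tok, lp in spans:
                post = np.exp(alpha[j] + lp + beta[i] - alpha[n])
                if post > 0:
                    expected[tok] = expected.get(tok, 0.0) + c * post
        return expected

    @staticmethod
    def _m_step(
        expected: dict[str, float], probs: dict[str, float], singles: set[str]
    ) -> dict[str, float]:
        floor = 1e-6
        weights = {}
        for t in probs:
            w = expected.get(t, 0.0)
            if t in singles:
                w = max(w, floor)  # singles are never dropped
            if w > 0:
                weights[t] = w
        return UnigramTokenizer._normalize(weights)

    def _finalize(self, probs: dict[str, float], alphabet: list[str]) -> None:
        order = sorted(probs, key=lambda t: (-probs[t], t))
        self.pieces_ = {t: i + 2 for i, t in enumerate(order)}
        self.log_probs_ = {t: probs[t] for t in order}
        self.alphabet_ = list(alphabet)
        self.vocab_ = [(t, probs[t]) for t in order]
        self._max_piece_len = max(len(t) for t in order)
        self._unk_logp = min(probs.values()) - _UNK_PENALTY

    @classmethod
    def from_vocab(
        cls, pieces: dict[str, float], max_len: int = 128
    ) -> "UnigramTokenizer":
        """Build a fitted tokenizer from an explicit {piece: log-prob} table."""
        tok = cls(vocab_size=len(pieces), max_len=max_len)
        alphabet = sorted({c for t in pieces for c in t})
        tok._finalize(dict(pieces), alphabet)
        return tok

    # -- segmentation ---------------------------------------------------------
    def segment(self, sequence: str) -> list[str]:
        """Viterbi (maximum-likelihood) segmentation into surface pieces.

        Concatenating the returned pieces reconstructs the input exactly;
        characters outside the vocabulary become single-character pieces
        that encode to the unk id.
        """
        self._check_fitted()
        n = len(sequence)
        if n == 0:
            return []
        best = np.full(n + 1, -np.inf)
        best[0] = 0.0
        back: list[int] = [0] * (n + 1)
        for i in range(1, n + 1):
            for L in range(1, min(self._max_piece_len, i) + 1):
                tok = sequence[i - L : i]
                lp = self.log_probs_.get(tok)
                if lp is None:
                    if L == 1:
                        lp = self._unk_logp  # unknown char, its own piece
                    else:
                        continue
                cand = best[i - L] + lp
                if cand > best[i]:
                    best[i] = cand
                    back[i] = i - L
        pieces = []
        i = n
        while i > 0:
            j = back[i]
            pieces.append(sequence[j:i])
            i = j
        return pieces[::-1]

    def segmentation_logprob(self, sequence: str) -> float:
        """Log-likelihood of the Viterbi segmentation."""
        return float(
            sum(self.log_probs_.get(p, self._unk_logp) for p in self.segment(sequence))
        )

    def encode(self, sequence: str, max_len: int | None = None) -> TokenSequence:
        """Segment, map to ids, truncate from the tail, pad to max_len."""
        self._check_fitted()
        max_len = self.max_len if max_len is None else max_len
        if max_len < 1:
            raise ValueError("max_len must be positive")
        pieces = self.segment(sequence)
        ids_full = [self.pieces_.get(p, UNK_ID) for p in pieces]
        n = min(len(ids_full), max_len)
        ids = np.full(max_len, PAD_ID, dtype=np.int64)
        mask = np.zeros(max_len, dtype=bool)
        ids[:n] = ids_full[:n]
        mask[:n] = True
        return TokenSequence(ids=ids, mask=mask, original_length=len(ids_full))

    def transform(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Encode an iterable of strings to stacked (ids, mask) arrays."""
        encoded = [self.encode(s) for s in X]
        return (
            np.stack([e.ids for e in encoded]),
            np.stack([e.mask for e in encoded]),
        )

    @property
    def n_ids(self) -> int:
        """Total id space (specials + pieces)."""
        self._check_fitted()
        return len(self.pieces_) + 2

    def _check_fitted(self):
        if not hasattr(self, "pieces_"):
            raise RuntimeError("tokenizer is not fitted; call fit() or load()")

    # -- serialization --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "format": _FORMAT,
            "version": _VERSION,
            "pad_id": PAD_ID,
            "unk_id": UNK_ID,
            "character_level": self.character_level,
            "max_len": self.max_len,
            "alphabet": self.alphabet_,
            "pieces": [[t, lp] for t, lp in self.vocab_],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "UnigramTokenizer":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a {_FORMAT} model file")
        if payload.get("version") != _VERSION:
            raise ValueError(f"{path}: unsupported model version {payload.get('version')}")
        tok = cls(
            vocab_size=len(payload["pieces"]),
            max_len=payload.get("max_len", 128),
            character_level=payload.get("character_level", False),
        )
        tok._finalize({t: lp for t, lp in payload["pieces"]}, payload["alphabet"])
        return tok


def train_unigram_tokenizer(
    corpus, vocab_size: int, seed: int = 0, **kwargs
) -> UnigramTokenizer:
    """Fit a :class:`UnigramTokenizer` on a corpus of strings."""
    return UnigramTokenizer(vocab_size=vocab_size, seed=seed, **kwargs).fit(corpus)


def encode(model: UnigramTokenizer, sequence: str, max_len: int) -> TokenSequence:
    """Functional form of :meth:`UnigramTokenizer.encode`."""
    return model.encode(sequence, max_len)
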