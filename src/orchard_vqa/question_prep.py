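"""Question text pipeline: normalization, word-piece tokenization with
fixed-length padding (26 tokens), OOV least-squares projection, text
augmentation, and the question-encoder contract.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import BackendNotInstalledError, InvalidInputError

__all__ = [
    "MAX_LEN", "TokenSeq", "QuestionFeature", "OOVProjection",
    "WordPieceVocab", "normalize_text", "tokenize_and_pad",
    "fit_oov_projection", "encode_question", "augment_text",
    "register_question_encoder", "ENCODER_DIMS",
]

MAX_LEN = 26
PAD, UNK = "[PAD]", "[UNK]"

# Pooled dimension J per encoder mode.
ENCODER_DIMS = {"skipthought": 2400, "bert": 768, "recurrent": 1024}

_PUNCT_RE = re.compile("[" + re.escape(string.punctuation) + "]")


def normalize_text(text: str) -> str:
    """Lower-case, replace punctuation by spaces, collapse whitespace.

    Punctuation becomes a space rather than vanishing inline so that "a,b"
    cannot fuse into "ab".
    """
    return " ".join(_PUNCT_RE.sub(" ", text.lower()).split())


@dataclass
class TokenSeq:
    tokens: list[int]          # exactly MAX_LEN ids
    mask: list[bool]           # True = real token
    raw: str

    def __post_init__(self):
        if len(self.tokens) != MAX_LEN or len(self.mask) != MAX_LEN:
            raise InvalidInputError(f"token sequences must have length {MAX_LEN}")


@dataclass
class QuestionFeature:
    sequence: np.ndarray       # MAX_LEN x d, masked rows zeroed
    pooled: np.ndarray         # J-vector
    mask: np.ndarray           # MAX_LEN booleans

    @property
    def d_q(self) -> int:
        return int(self.pooled.shape[0])


class WordPieceVocab:
    """Word-piece vocabulary trained by BPE-style merges, greedy-longest-match
    tokenization.  Ids 0/1 are reserved for PAD/UNK."""

    def __init__(self, pieces: list[str]):
        if pieces[:2] != [PAD, UNK]:
            pieces = [PAD, UNK] + [p for p in pieces if p not in (PAD, UNK)]
        self.pieces = pieces
        self.index = {p: i for i, p in enumerate(pieces)}

    def __len__(self):
        return len(self.pieces)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    # -- training ----------------------------------------------------------

    @classmethod
    def train(cls, texts: list[str], size_cap: int = 4000) -> "WordPieceVocab":
        words = Counter()
        for t in texts:
            words.update(normalize_text(t).split())
        if not words:
            raise InvalidInputError("cannot train a vocabulary on empty text")
        # seed pieces: every starting char and every continuation char
        pieces: list[str] = [PAD, UNK]
        seen = set(pieces)
        for w in words:
            for i, ch in enumerate(w):
                p = ch if i == 0 else "##" + ch
                if p not in seen:
                    seen.add(p)
                    pieces.append(p)
        # BPE merges over within-word adjacent piece pairs
        splits = {w: [w[0]] + ["##" + c for c in w[1:]] for w in words}
        while len(pieces) < size_cap:
            pairs: Counter = Counter()
            for w, parts in splits.items():
                for a, b in zip(parts, parts[1:]):
                    pairs[(a, b)] += words[w]
            if not pairs:
                break
            (a, b), count = pairs.most_common(1)[0]
            if count < 2:
                break
            merged = a + b[2:]
            if merged in seen:
                break
            seen.add(merged)
            pieces.append(merged)
            for w, parts in splits.items():
                out, i = [], 0
                while i < len(parts):
                    if i + 1 < len(parts) and parts[i] == a and parts[i + 1] == b:
                        out.append(merged)
                        i += 2
                    else:
                        out.append(parts[i])
                        i += 1
                splits[w] = out
        return cls(pieces)

    # -- tokenization ------------------------------------------------------

    def word_to_pieces(self, word: str) -> list[str]:
        out, start = [], 0
        while start < len(word):
            end, piece = len(word), None
            while end > start:
                cand = word[start:end] if start == 0 else "##" + word[start:end]
                if cand in self.index:
                    piece = cand
                    break
                end -= 1
            if piece is None:
                return [UNK]
            out.append(piece)
            start = end
        return out

    def encode(self, text: str) -> list[int]:
        ids = []
        for word in normalize_text(text).split():
            ids.extend(self.index.get(p, self.unk_id)
                       for p in self.word_to_pieces(word))
        return ids

    # -- persistence (token per line) --------------------------------------

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.pieces) + "\n")

    @classmethod
    def load(cls, path) -> "WordPieceVocab":
        with open(path, encoding="utf-8") as fh:
            return cls([line.rstrip("\n") for line in fh if line.strip()])


def tokenize_and_pad(text: str, vocab: WordPieceVocab,
                     max_len: int = MAX_LEN) -> TokenSeq:
    """Greedy word-piece split, zero-padded or truncated to `max_len`."""
    ids = vocab.encode(text)[:max_len]
    mask = [True] * len(ids) + [False] * (max_len - len(ids))
    ids = ids + [vocab.pad_id] * (max_len - len(ids))
    return TokenSeq(tokens=ids, mask=mask, raw=normalize_text(text))


# ---------------------------------------------------------------------------
# OOV projection (weighted least squares into the sentence-embedding space)
# ---------------------------------------------------------------------------

@dataclass
class OOVProjection:
    matrix: np.ndarray          # source_dim x target_dim
    residual: float             # Frobenius norm of the training residual

    def __call__(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.matrix


def fit_oov_projection(source: np.ndarray, target: np.ndarray,
                       weights: np.ndarray | None = None) -> OOVProjection:
    """Weighted least-squares linear map source -> target.

    Weights default to uniform.  Underdetermined systems resolve to the
    minimum-norm solution (via `lstsq`).
    """
    source = np.atleast_2d(np.asarray(source, dtype=np.float64))
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if source.shape[0] != target.shape[0]:
        raise InvalidInputError(
            f"paired rows required: {source.shape[0]} != {target.shape[0]}")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=np.float64))
        if w.shape[0] != source.shape[0]:
            raise InvalidInputError("one weight per row required")
        source = source * w[:, None]
        target = target * w[:, None]
    matrix, _, _, _ = np.linalg.lstsq(source, target, rcond=None)
    residual = float(np.linalg.norm(source @ matrix - target))
    return OOVProjection(matrix=matrix, residual=residual)


# ---------------------------------------------------------------------------
# Question encoding
# ---------------------------------------------------------------------------

_Q_REGISTRY: dict[str, object] = {}


def register_question_encoder(mode: str, fn) -> None:
    """Register `fn(seq: TokenSeq, dim: int, seed: int) -> (MAX_LEN x d, mask)`
    as the backend for `mode`."""
    _Q_REGISTRY[mode] = fn


def _tiny_encoder(seq: TokenSeq, dim: int, seed: int) -> np.ndarray:
    """Seeded hash-embedding: each token id maps to a fixed random vector."""
    out = np.zeros((MAX_LEN, dim))
    for i, (tok, real) in enumerate(zip(seq.tokens, seq.mask)):
        if real:
            out[i] = np.random.default_rng([seed, tok]).normal(size=dim)
    return out


register_question_encoder("tiny", _tiny_encoder)


def encode_question(seq: TokenSeq, mode: str = "tiny", dim: int = 32,
                    seed: int = 0) -> QuestionFeature:
    """Encode a token sequence; pooled vector is the masked mean.

    `mode` is one of {tiny, skipthought, bert, recurrent}; the non-tiny
    backends are optional plug-ins and raise if not registered.  An all-pad
    sequence pools to the zero vector.
    """
    if mode in ENCODER_DIMS:
        dim = ENCODER_DIMS[mode]
    if mode not in _Q_REGISTRY:
        if mode in ENCODER_DIMS:
            raise BackendNotInstalledError(
                f"question encoder backend {mode!r} is an optional plug-in "
                f"and is not installed; register it with "
                f"register_question_encoder()")
        raise InvalidInputError(f"unknown encoder mode {mode!r}")
    sequence = np.asarray(_Q_REGISTRY[mode](seq, dim, seed), dtype=np.float64)
    mask = np.asarray(seq.mask, dtype=bool)
    sequence = sequence * mask[:, None]      # never read masked positions
    n_real = int(mask.sum())
    pooled = sequence[mask].mean(axis=0) if n_real else np.zeros(dim)
    return QuestionFeature(sequence=sequence, pooled=pooled, mask=mask)


# ---------------------------------------------------------------------------
# Text augmentation
# ---------------------------------------------------------------------------

def augment_text(text: str, seed: int = 0,
                 lexicon: dict[str, list[str]] | None = None,
                 templates: list[str] | None = None,
                 noise_rate: float = 0.05) -> list[str]:
    """Variants by word replacement, single-word deletion, character noise,
    and template resampling.  One-word inputs skip the deletion operator."""
    norm = normalize_text(text)
    if not norm:
        raise InvalidInputError("cannot augment empty text")
    rng = np.random.default_rng(seed)
    words = norm.split()
    variants: list[str] = []

    # replacement from the lexicon (unchanged text when lexicon is empty)
    replaced = list(words)
    if lexicon:
        idxs = [i for i, w in enumerate(words) if lexicon.get(w)]
        if idxs:
            i = idxs[int(rng.integers(len(idxs)))]
            options = lexicon[words[i]]
            replaced[i] = options[int(rng.integers(len(options)))]
    variants.append(" ".join(replaced))

    # single-word deletion
    if len(words) > 1:
        i = int(rng.integers(len(words)))
        variants.append(" ".join(words[:i] + words[i + 1:]))

    # character-level noise at `noise_rate`
    alphabet = string.ascii_lowercase
    chars = list(norm)
    flips = rng.random(len(chars)) < noise_rate
    for i, flip in enumerate(flips):
        if flip and chars[i] != " ":
            chars[i] = alphabet[int(rng.integers(26))]
    variants.append("".join(chars))

    # template resampling
    if templates:
        variants.append(normalize_text(
            templates[int(rng.integers(len(templates)))]))
    return variants
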