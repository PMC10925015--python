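"""Frequency-merged substructure vocabulary and tokenizer for SMILES.

Byte-pair-encoding-style decomposition: SMILES strings are split into single
characters and the most frequent adjacent token pair is merged repeatedly,
until the best pair's corpus frequency drops below the threshold ``mu`` or
the vocabulary reaches the size cap ``delta``.  Pair counting is
per-adjacent-occurrence, non-overlapping left-to-right within a string; ties
are broken lexicographically on the (left, right) pair so the merge list is
byte-stable and replayable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import UnknownCharError

logger = logging.getLogger(__name__)

DEFAULT_MU = 2
DEFAULT_DELTA = 2000
DEFAULT_ZETA = 64


@dataclass
class EspfVocab:
    """Merged-token vocabulary: initial characters plus recorded merges."""
    tokens: list[str]
    merges: list[tuple[str, str]]
    mu: int
    delta: int

    @property
    def token_to_id(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def save(self, path: str | Path) -> None:
        lines = [f"# mu={self.mu}", f"# delta={self.delta}",
                 "# alphabet=" + "".join(t for t in self.tokens
                                         if len(t) == 1)]
        lines += [f"{a}\t{b}" for a, b in self.merges]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EspfVocab":
        mu = delta = None
        alphabet = ""
        merges: list[tuple[str, str]] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("# mu="):
                mu = int(line.split("=", 1)[1])
            elif line.startswith("# delta="):
                delta = int(line.split("=", 1)[1])
            elif line.startswith("# alphabet="):
                alphabet = line.split("=", 1)[1]
            elif line:
                a, b = line.split("\t")
                merges.append((a, b))
        tokens = list(alphabet) + [a + b for a, b in merges]
        return cls(tokens=tokens, merges=merges, mu=mu, delta=delta)


@dataclass
class SubstructureSequence:
    """A drug's token-id sequence padded/truncated to ``zeta`` positions."""
    token_ids: list[int]
    tokens: list[str]
    length: int
    max_len: int
    pad_mask: np.ndarray  # bool (zeta,), True at real-token positions


def _count_pairs(corpus_tokens: list[list[str]]) -> Counter:
    """Adjacent-pair counts, non-overlapping left-to-right per string."""
    counts: Counter = Counter()
    for toks in corpus_tokens:
        i = 0
        while i < len(toks) - 1:
            counts[(toks[i], toks[i + 1])] += 1
            i += 2 if toks[i] == toks[i + 1] else 1
    return counts


def _apply_merge(toks: list[str], pair: tuple[str, str]) -> list[str]:
    """Replace non-overlapping left-to-right occurrences of `pair`."""
    a, b = pair
    out: list[str] = []
    i = 0
    while i < len(toks):
        if i < len(toks) - 1 and toks[i] == a and toks[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(toks[i])
            i += 1
    return out


def build_vocab(corpus: list[str], mu: int = DEFAULT_MU,
                delta: int = DEFAULT_DELTA) -> EspfVocab:
    """Greedy pair-merging over a SMILES corpus.

    Stops when the most frequent adjacent pair occurs fewer than ``mu`` times
    or the vocabulary holds ``delta`` tokens.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if mu < 2:
        raise ValueError("mu must be >= 2")
    alphabet = sorted({ch for s in corpus for ch in s})
    if delta < len(alphabet):
        raise ValueError("delta smaller than the corpus alphabet")
    tokens = list(alphabet)
    merges: list[tuple[str, str]] = []
    corpus_tokens = [list(s) for s in corpus]
    while len(tokens) < delta:
        counts = _count_pairs(corpus_tokens)
        if not counts:
            break
        # highest count first; lexicographic (left, right) breaks ties
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        pair, freq = best
        if freq < mu:
            break
        merges.append(pair)
        tokens.append(pair[0] + pair[1])
        corpus_tokens = [_apply_merge(toks, pair) for toks in corpus_tokens]
    return EspfVocab(tokens=tokens, merges=merges, mu=mu, delta=delta)


def tokenize(smiles: str, vocab: EspfVocab,
             zeta: int = DEFAULT_ZETA) -> SubstructureSequence:
    """Split to characters, replay recorded merges, map to ids, pad to zeta."""
    if not smiles:
        raise ValueError("empty SMILES")
    tok2id = vocab.token_to_id
    for ch in smiles:
        if ch not in tok2id:
            raise UnknownCharError(
                f"character {ch!r} absent from vocabulary alphabet")
    toks = list(smiles)
    for pair in vocab.merges:
        toks = _apply_merge(toks, pair)
    if len(toks) > zeta:
        logger.warning("sequence of %d tokens truncated to zeta=%d",
                       len(toks), zeta)
        toks = toks[:zeta]
    ids = [tok2id[t] for t in toks]
    mask = np.zeros(zeta, dtype=bool)
    mask[:len(ids)] = True
    return SubstructureSequence(token_ids=ids, tokens=toks, length=len(ids),
                                max_len=zeta, pad_mask=mask)
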