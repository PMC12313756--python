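"""k-mer tokenization schemes for genomic language models.

Three schemes are supported:

``overlapping``
    A k-mer is emitted at every 1-bp offset, so consecutive tokens share
    k - 1 bases.  A sequence of length L yields L - k + 1 content tokens.

``nonoverlapping``
    The sequence is partitioned into consecutive disjoint k-bp blocks,
    yielding ceil(L / k) content tokens.  A trailing remainder of length
    L mod k is emitted as a single [UNK] token spanning the leftover bases,
    which keeps the ceil(L/k) token count exact without enlarging the
    4**k + 5 vocabulary.

``agront6``
    AgroNT-style greedy 6-mer segmentation: 6-mers are emitted whenever the
    next six bases are N-free and at least six bases remain; otherwise a
    single-nucleotide token (A, C, G, T or N) is emitted and segmentation
    resumes.  Only this scheme carries the five single-character tokens.

The vocabulary for the generic schemes has exactly 4**k + 5 entries: the
five special tokens [PAD], [MASK], [CLS], [SEP], [UNK] at ids 0-4 followed
by all k-mers over {A, C, G, T} in lexicographic order.  All coordinates are
0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SPECIAL_TOKENS",
    "PAD_ID",
    "MASK_ID",
    "CLS_ID",
    "SEP_ID",
    "UNK_ID",
    "SCHEMES",
    "TokenizerSpec",
    "TokenizedSequence",
    "build_vocab",
    "tokenize",
    "expected_token_count",
    "detokenize",
    "tokens_overlapping_position",
    "write_vocab",
    "read_vocab",
]

SPECIAL_TOKENS = ("[PAD]", "[MASK]", "[CLS]", "[SEP]", "[UNK]")
PAD_ID, MASK_ID, CLS_ID, SEP_ID, UNK_ID = range(5)

AGRONT_SINGLES = ("A", "C", "G", "T", "N")
SCHEMES = ("overlapping", "nonoverlapping", "agront6")

_ALPHABET = "ACGT"
_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class TokenizerSpec:
    """Immutable description of a k-mer tokenizer.

    Attributes
    ----------
    k : int
        Window size, 3..8 (fixed at 6 for the ``agront6`` scheme).
    scheme : str
        One of :data:`SCHEMES`.
    vocab : dict[str, int]
        Bijective token-string -> id mapping.  Special tokens occupy
        ids 0-4; k-mers follow in lexicographic order.
    """

    k: int
    scheme: str
    vocab: dict[str, int] = field(repr=False)
    id_to_token: tuple[str, ...] = field(repr=False)

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @property
    def special_tokens(self) -> tuple[str, ...]:
        return SPECIAL_TOKENS

    def is_special_id(self, token_id: int) -> bool:
        """True for [PAD]/[MASK]/[CLS]/[SEP]/[UNK] ids."""
        return token_id < len(SPECIAL_TOKENS)

    def content_ids(self) -> range:
        """Ids of the plain k-mer tokens (excludes specials and singles)."""
        return range(len(SPECIAL_TOKENS), len(SPECIAL_TOKENS) + 4**self.k)


@dataclass
class TokenizedSequence:
    """Token ids plus per-content-token genomic spans.

    ``spans[i]`` is the 0-based half-open base interval of ``token_ids[i]``
    in the source sequence, or ``None`` for sentinel ([CLS]/[SEP]) tokens.
    """

    token_ids: list[int]
    spans: list[tuple[int, int] | None]
    source_length: int
    has_sentinels: bool

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def content_indices(self) -> range:
        """Indices into token_ids that carry a genomic span."""
        if self.has_sentinels:
            return range(1, len(self.token_ids) - 1)
        return range(len(self.token_ids))


def build_vocab(k: int, scheme: str) -> TokenizerSpec:
    """Construct the deterministic vocabulary for a scheme.

    Special tokens sit at ids 0-4, then all 4**k k-mers in lexicographic
    order; the agront6 scheme appends the five single-character tokens
    A, C, G, T, N.

    Raises
    ------
    ValueError
        If k is outside [3, 8], the scheme is unknown, or agront6 is
        requested with k != 6.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not 3 <= k <= 8:
        raise ValueError(f"k must be in [3, 8], got {k}")
    if scheme == "agront6" and k != 6:
        raise ValueError(f"agront6 tokenization is defined for k=6 only, got k={k}")

    tokens = list(SPECIAL_TOKENS)
    tokens.extend("".join(p) for p in itertools.product(_ALPHABET, repeat=k))
    if scheme == "agront6":
        tokens.extend(AGRONT_SINGLES)
    vocab = {tok: i for i, tok in enumerate(tokens)}
    return TokenizerSpec(k=k, scheme=scheme, vocab=vocab, id_to_token=tuple(tokens))


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    bad = set(sequence) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"sequence contains characters outside ACGTN: {sorted(bad)}"
        )


def tokenize(
    sequence: str, spec: TokenizerSpec, add_sentinels: bool = False
) -> TokenizedSequence:
    """Tokenize an uppercase ACGTN sequence under the spec's scheme.

    Generic schemes map any window containing N to [UNK] (the span is
    retained).  The nonoverlapping remainder of length L mod k becomes one
    [UNK] token.  With ``add_sentinels`` the token list is wrapped in
    [CLS] ... [SEP], adding two tokens that carry no span.
    """
    _validate_sequence(sequence)
    L = len(sequence)
    k = spec.k
    vocab = spec.vocab

    ids: list[int] = []
    spans: list[tuple[int, int] | None] = []

    if spec.scheme == "overlapping":
        if L < k:
            raise ValueError(
                f"overlapping tokenization needs length >= k ({k}), got {L}"
            )
        for start in range(L - k + 1):
            ids.append(vocab.get(sequence[start : start + k], UNK_ID))
            spans.append((start, start + k))
    elif spec.scheme == "nonoverlapping":
        full_blocks = L // k
        for b in range(full_blocks):
            start = b * k
            ids.append(vocab.get(sequence[start : start + k], UNK_ID))
            spans.append((start, start + k))
        if L % k:
            ids.append(UNK_ID)
            spans.append((full_blocks * k, L))
    else:  # agront6
        pos = 0
        while pos < L:
            window = sequence[pos : pos + 6]
            if len(window) == 6 and "N" not in window:
                ids.append(vocab[window])
                spans.append((pos, pos + 6))
                pos += 6
            else:
                ids.append(vocab[sequence[pos]])
                spans.append((pos, pos + 1))
                pos += 1

    if add_sentinels:
        ids = [CLS_ID, *ids, SEP_ID]
        spans = [None, *spans, None]

    return TokenizedSequence(
        token_ids=ids, spans=spans, source_length=L, has_sentinels=add_sentinels
    )


def expected_token_count(
    L: int, k: int, scheme: str, with_sentinels: bool = True
) -> int:
    """Closed-form token count T_k for an N-free sequence of length L.

    nonoverlapping: ceil(L / k) + 2;  overlapping: L - k + 1 + 2.  The +2
    accounts for [CLS]/[SEP]; without sentinels it is dropped.  agront6 on
    N-free input follows the nonoverlapping 6-mer count with the remainder
    split into singles instead of one [UNK], i.e. ``L // 6 + L % 6``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if L < 1:
        raise ValueError("L must be positive")
    if scheme == "overlapping":
        if L < k:
            raise ValueError(f"overlapping scheme requires L >= k, got L={L}, k={k}")
        count = L - k + 1
    elif scheme == "nonoverlapping":
        count = -(-L // k)
    else:
        count = L // 6 + L % 6
    return count + 2 if with_sentinels else count


def detokenize(tok: TokenizedSequence, spec: TokenizerSpec) -> str:
    """Reconstruct the source sequence from its tokens.

    Overlapping: first token plus the last character of each subsequent
    token.  Nonoverlapping / agront6: plain concatenation.  [UNK] tokens
    make reconstruction lossy and raise.
    """
    content = [
        (tok.token_ids[i], tok.spans[i]) for i in tok.content_indices
    ]
    if any(tid == UNK_ID for tid, _ in content):
        raise ValueError("cannot detokenize: [UNK] tokens are lossy")
    strings = [spec.id_to_token[tid] for tid, _ in content]
    if not strings:
        return ""
    if spec.scheme == "overlapping":
        out = strings[0] + "".join(s[-1] for s in strings[1:])
    else:
        out = "".join(strings)
    if len(out) != tok.source_length:
        raise ValueError(
            f"reconstructed length {len(out)} != source_length {tok.source_length}"
        )
    return out


def tokens_overlapping_position(tok: TokenizedSequence, position: int) -> set[int]:
    """Indices of content tokens whose span contains a 0-based position.

    Returned indices index into ``tok.token_ids`` (so they are shifted by
    one when sentinels are present); sentinel tokens are never included.
    """
    if not 0 <= position < tok.source_length:
        raise ValueError(
            f"position {position} out of range [0, {tok.source_length})"
        )
    return {
        i
        for i in tok.content_indices
        if tok.spans[i] is not None and tok.spans[i][0] <= position < tok.spans[i][1]
    }


def write_vocab(spec: TokenizerSpec, path: str | Path) -> None:
    """Write the vocabulary as plain text, one token per line (line - 1 = id)."""
    Path(path).write_text("\n".join(spec.id_to_token) + "\n")


def read_vocab(path: str | Path, k: int, scheme: str) -> TokenizerSpec:
    """Read a vocabulary file written by :func:`write_vocab` and verify it."""
    tokens = Path(path).read_text().splitlines()
    expected = build_vocab(k, scheme)
    if tuple(tokens) != expected.id_to_token:
        raise ValueError(f"vocabulary in {path} does not match k={k}, {scheme}")
    return expected
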