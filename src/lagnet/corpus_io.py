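"""Reading, validating and editing verbal-fluency response chains.

A fluency (lexical availability) task asks an informant to list, in order,
as many words as they can for a cue category such as *animals*.  The raw
unit of analysis is therefore an ordered chain of word tokens per informant
per prompt.  Before any graph is built the chains are edited: spelling is
corrected from a user-supplied table, multi-word responses are joined into
a single token (``fresh air`` -> ``fresh-air``), case is folded, and
repetitions within a chain are removed keeping the first occurrence.

Two on-disk dialects are supported:

``long``
    CSV/TSV with header ``informant_id,prompt,position,word`` and one row
    per produced token; positions are 1-based and contiguous per chain.
``lines``
    One chain per line, ``informant_id: w1, w2, w3``.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ResponseChain",
    "Corpus",
    "EditRules",
    "EditEvent",
    "EditResult",
    "CorpusFormatError",
    "EmptyCorpusError",
    "read_chains",
    "edit_corpus",
    "write_corpus",
    "write_edit_log",
]


class CorpusFormatError(ValueError):
    """Malformed input file (missing columns, gaps, duplicate rows)."""


class EmptyCorpusError(ValueError):
    """The input contained no usable chains."""


@dataclass(frozen=True)
class ResponseChain:
    """One informant's ordered word sequence for one prompt.

    Positions are implicit: ``words[i]`` sits at 1-based position ``i + 1``.
    """

    informant_id: str
    prompt: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.words) < 1:
            raise ValueError("a response chain needs at least one word")
        for w in self.words:
            if not w or w != w.strip():
                raise ValueError(f"token {w!r} is empty or untrimmed")

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class Corpus:
    """All chains elicited by one prompt; at most one chain per informant."""

    prompt: str
    chains: tuple[ResponseChain, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ch in self.chains:
            if ch.prompt != self.prompt:
                raise ValueError(
                    f"chain prompt {ch.prompt!r} != corpus prompt {self.prompt!r}"
                )
            if ch.informant_id in seen:
                raise ValueError(
                    f"informant {ch.informant_id!r} has more than one chain"
                )
            seen.add(ch.informant_id)

    @property
    def informant_count(self) -> int:
        """Number of distinct informants (the sample size I1)."""
        return len(self.chains)

    def __len__(self) -> int:
        return len(self.chains)


@dataclass(frozen=True)
class EditRules:
    """Data-editing policy for raw chains.

    Defaults mirror standard practice for availability corpora: fold case,
    hyphenate multi-word answers, drop within-chain repetitions keeping the
    first occurrence.  Spelling correction is table-driven and off unless a
    map is supplied — automatic correction would be uncontrolled.
    """

    lowercase: bool = True
    dedupe_within_chain: bool = True
    multiword_joiner: str = "-"
    spelling_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.multiword_joiner or any(c.isspace() for c in self.multiword_joiner):
            raise ValueError("multiword_joiner must be a non-space token")
        if self.spelling_map:
            for k, v in self.spelling_map.items():
                if not k or not v:
                    raise ValueError("spelling_map keys and values must be non-empty")


@dataclass(frozen=True)
class EditEvent:
    informant_id: str
    original: str
    edited: str
    rule: str


@dataclass(frozen=True)
class EditResult:
    corpus: Corpus
    log: tuple[EditEvent, ...] = field(default_factory=tuple)


def _read_long(path: Path, prompt: str | None) -> Corpus:
    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if "\t" in sample.split("\n", 1)[0] else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"informant_id", "prompt", "position", "word"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CorpusFormatError(
                f"{path}: long dialect needs columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        rows: dict[tuple[str, str], dict[int, str]] = {}
        for lineno, row in enumerate(reader, start=2):
            inf, prm = row["informant_id"].strip(), row["prompt"].strip()
            if prompt is not None and prm != prompt:
                continue
            try:
                pos = int(row["position"])
            except (TypeError, ValueError):
                raise CorpusFormatError(
                    f"{path}:{lineno}: position {row['position']!r} is not an integer"
                ) from None
            word = (row["word"] or "").strip()
            if not word:
                raise CorpusFormatError(f"{path}:{lineno}: empty word")
            chain = rows.setdefault((inf, prm), {})
            if pos in chain:
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate position {pos} for informant "
                    f"{inf!r}, prompt {prm!r}"
                )
            chain[pos] = word
    if not rows:
        raise EmptyCorpusError(f"{path}: no chains found")
    prompts = {prm for _, prm in rows}
    if prompt is None:
        if len(prompts) > 1:
            raise CorpusFormatError(
                f"{path}: multiple prompts {sorted(prompts)}; pass prompt= to select one"
            )
        prompt = prompts.pop()
    chains = []
    for (inf, prm), by_pos in sorted(rows.items()):
        expected = list(range(1, len(by_pos) + 1))
        if sorted(by_pos) != expected:
            raise CorpusFormatError(
                f"{path}: informant {inf!r}, prompt {prm!r}: positions "
                f"{sorted(by_pos)} are not contiguous 1..{len(by_pos)}"
            )
        chains.append(ResponseChain(inf, prm, tuple(by_pos[p] for p in expected)))
    return Corpus(prompt, tuple(chains))


def _read_lines(path: Path, prompt: str | None) -> Corpus:
    prompt = prompt or "unknown"
    chains = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'informant_id: w1, w2, ...'"
                )
            inf, _, rest = line.partition(":")
            words = tuple(w.strip() for w in rest.split(",") if w.strip())
            if not words:
                raise CorpusFormatError(f"{path}:{lineno}: chain has no words")
            chains.append(ResponseChain(inf.strip(), prompt, words))
    if not chains:
        raise EmptyCorpusError(f"{path}: no chains found")
    return Corpus(prompt, tuple(chains))


def read_chains(path: str | Path, dialect: str = "long", prompt: str | None = None) -> Corpus:
    """Read a fluency corpus from disk.

    Parameters
    ----------
    path : file path
    dialect : ``"long"`` or ``"lines"`` (see module docstring)
    prompt : restrict a long file to one prompt; mandatory when the file
        mixes prompts.  For the lines dialect it labels the corpus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        return _read_long(path, prompt)
    if dialect == "lines":
        return _read_lines(path, prompt)
    raise ValueError(f"unknown dialect {dialect!r}")


def _edit_chain(chain: ResponseChain, rules: EditRules, log: list[EditEvent]) -> ResponseChain | None:
    out: list[str] = []
    seen: set[str] = set()
    smap = rules.spelling_map or {}
    for token in chain.words:
        word = token
        if word in smap:
            word = smap[word]
            log.append(EditEvent(chain.informant_id, token, word, "spelling"))
        if any(c.isspace() for c in word):
            joined = rules.multiword_joiner.join(word.split())
            log.append(EditEvent(chain.informant_id, word, joined, "multiword"))
            word = joined
        if rules.lowercase and word != word.lower():
            log.append(EditEvent(chain.informant_id, word, word.lower(), "lowercase"))
            word = word.lower()
        if rules.dedupe_within_chain and word in seen:
            log.append(EditEvent(chain.informant_id, word, "", "repetition-removed"))
            continue
        seen.add(word)
        out.append(word)
    if not out:
        return None
    return replace(chain, words=tuple(out))


def edit_corpus(corpus: Corpus, rules: EditRules | None = None) -> EditResult:
    """Apply the editing criteria to every chain.

    Repetitions within a chain are removed (first occurrence kept) and
    positions recompact to 1..L', so downstream positional statistics see
    gap-free ranks.  A chain emptied by editing is dropped with a warning.
    Idempotent: editing an already-edited corpus is a no-op.
    """
    rules = rules or EditRules()
    log: list[EditEvent] = []
    chains = []
    for chain in corpus.chains:
        edited = _edit_chain(chain, rules, log)
        if edited is None:
            warnings.warn(
                f"chain of informant {chain.informant_id!r} emptied by editing; dropped",
                stacklevel=2,
            )
            continue
        chains.append(edited)
    return EditResult(Corpus(corpus.prompt, tuple(chains)), tuple(log))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the long dialect (UTF-8 CSV)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["informant_id", "prompt", "position", "word"])
        for chain in corpus.chains:
            for pos, word in enumerate(chain.words, start=1):
                w.writerow([chain.informant_id, chain.prompt, pos, word])


def write_edit_log(log: Iterable[EditEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain_id", "original", "edited", "rule"])
        for ev in log:
            w.writerow([ev.informant_id, ev.original, ev.edited, ev.rule])
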