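"""End-to-end orchestration: query -> literature -> target -> molecule -> pKi.

The pipeline runs over three pluggable providers so the whole graph executes
offline under mocks:

* ``llm``: text -> text, used once to extract protein-name abbreviations
  from retrieved abstracts as a ``*``-bulleted list;
* ``retriever``: query -> list of abstract strings;
* ``sequence_source``: protein name -> list of amino-acid sequences (the
  first record wins).

Stage results and failures accumulate on an :class:`AgentState`; a failing
stage halts the remaining stages and marks the state failed instead of
raising to the caller.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .clm import GenerationConfig, generate_batch
from .dti_rcnn import RcnnModel, predict_pki
from .tokenization import BpeTokenizer, CharVocab, encode_for_rcnn
from .data_io import LigandProteinPair

__all__ = [
    "EXTRACTION_INSTRUCTION",
    "AgentState",
    "ProviderBundle",
    "ProviderError",
    "TargetNotFoundError",
    "InvalidSequenceError",
    "MockLlm",
    "MockRetriever",
    "MockSequenceSource",
    "build_extraction_prompt",
    "parse_star_list",
    "extract_protein_names",
    "fetch_first_sequence",
    "run_pipeline",
]

EXTRACTION_INSTRUCTION = (
    "extract all best matches protein name abbreviations from a given text and "
    "list them using * (your output should only be this list without any other "
    "words and sentences)"
)

_SEQUENCE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

STAGES = (
    "retrieve",
    "extract_names",
    "choose_protein",
    "fetch_sequence",
    "generate",
    "trim",
    "predict",
)


class ProviderError(RuntimeError):
    """A provider failed on well-formed input."""


class TargetNotFoundError(ProviderError):
    """The sequence source has no record for the requested name."""


class InvalidSequenceError(ProviderError):
    """A returned sequence is not a plausible amino-acid string."""


@dataclass
class AgentState:
    """Mutable record threaded through the pipeline stages."""

    query: str
    model_option: str = "mock"
    retrieved_texts: list[str] = field(default_factory=list)
    protein_names: list[str] = field(default_factory=list)
    chosen_protein: str = ""
    protein_sequence: str = ""
    raw_smiles: str = ""
    trimmed_smiles: str = ""
    predicted_pki: float | None = None
    trace: list[tuple[str, str, str]] = field(default_factory=list)
    failed: bool = False

    def log(self, stage: str, status: str, message: str = "") -> None:
        self.trace.append((stage, status, message))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass(frozen=True)
class ProviderBundle:
    llm: Callable[[str], str]
    retriever: Callable[[str], list[str]]
    sequence_source: Callable[[str], list[str]]


# ---------------------------------------------------------------------------
# Mock providers (file-backed variants load the same shapes from JSON)
# ---------------------------------------------------------------------------


class MockLlm:
    """Returns a canned response (or per-substring responses) for any prompt."""

    def __init__(self, response: str = "", by_substring: dict[str, str] | None = None):
        self.response = response
        self.by_substring = by_substring or {}

    def __call__(self, prompt: str) -> str:
        for key, resp in self.by_substring.items():
            if key in prompt:
                return resp
        return self.response


class MockRetriever:
    """Maps queries to abstract lists; unknown queries yield no documents."""

    def __init__(self, corpus: dict[str, list[str]] | None = None):
        self.corpus = corpus or {}

    @classmethod
    def from_json(cls, path: str | Path) -> "MockRetriever":
        return cls(json.loads(Path(path).read_text()))

    def __call__(self, query: str) -> list[str]:
        return list(self.corpus.get(query, []))


class MockSequenceSource:
    """Maps protein names to lists of sequence records."""

    def __init__(self, records: dict[str, list[str]] | None = None):
        self.records = records or {}

    @classmethod
    def from_json(cls, path: str | Path) -> "MockSequenceSource":
        return cls(json.loads(Path(path).read_text()))

    def __call__(self, name: str) -> list[str]:
        if name not in self.records:
            raise TargetNotFoundError(f"no sequence records for {name!r}")
        return list(self.records[name])


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def build_extraction_prompt(context_text: str) -> str:
    """Append the fixed extraction instruction to the context text."""
    if not context_text:
        return EXTRACTION_INSTRUCTION
    return f"{context_text}\n{EXTRACTION_INSTRUCTION}"


def parse_star_list(llm_output: str) -> list[str]:
    """Parse a ``*``-bulleted list, ignoring non-bulleted lines.

    Returns the bullet payloads in order; never raises — an output with no
    bullets parses to an empty list.
    """
    names: list[str] = []
    for line in llm_output.splitlines():
        stripped = line.strip()
        if not stripped.startswith("*"):
            continue
        name = stripped.lstrip("*").strip()
        if name:
            names.append(name)
    return names


def extract_protein_names(
    texts: Sequence[str], llm: Callable[[str], str]
) -> list[str]:
    """One LLM call over the concatenated texts; deduplicated, order kept.

    Raises
    ------
    ProviderError
        If the LLM provider fails.
    """
    prompt = build_extraction_prompt("\n\n".join(texts))
    try:
        raw = llm(prompt)
    except Exception as exc:  # noqa: BLE001 - provider contract boundary
        raise ProviderError(f"LLM provider failed: {exc}") from exc
    seen: set[str] = set()
    names = []
    for name in parse_star_list(raw):
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def fetch_first_sequence(name: str, sequence_source: Callable[[str], list[str]]) -> str:
    """First sequence record for ``name``, uppercased and alphabet-checked.

    Raises
    ------
    TargetNotFoundError
        If the source yields no records.
    InvalidSequenceError
        If the first record contains non-amino-acid characters.
    """
    records = sequence_source(name)
    if not records:
        raise TargetNotFoundError(f"no sequence records for {name!r}")
    seq = records[0].upper()
    bad = sorted(set(seq) - _SEQUENCE_ALPHABET)
    if not seq or bad:
        raise InvalidSequenceError(
            f"sequence for {name!r} contains invalid characters: {bad!r}"
        )
    return seq


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    query: str,
    providers: ProviderBundle,
    clm_model,
    tokenizer: BpeTokenizer,
    rcnn_model: RcnnModel,
    char_vocab: CharVocab,
    gen_config: GenerationConfig | None = None,
    model_option: str = "mock",
) -> AgentState:
    """Run the full pipeline; failures halt downstream stages in-state.

    Stage order: retrieve -> extract names -> choose first name -> fetch
    first sequence -> generate -> trim -> predict pKi. The predicted pKi is
    set only when the trimmed SMILES is non-empty.
    """
    if gen_config is None:
        gen_config = GenerationConfig()
    state = AgentState(query=query, model_option=model_option)

    def fail(stage: str, message: str) -> AgentState:
        state.log(stage, "failed", message)
        state.failed = True
        return state

    try:
        state.retrieved_texts = providers.retriever(query)
    except Exception as exc:  # noqa: BLE001
        return fail("retrieve", str(exc))
    state.log("retrieve", "ok", f"{len(state.retrieved_texts)} document(s)")

    if not state.retrieved_texts:
        return fail("extract_names", "no documents retrieved")
    try:
        state.protein_names = extract_protein_names(state.retrieved_texts, providers.llm)
    except ProviderError as exc:
        return fail("extract_names", str(exc))
    if not state.protein_names:
        return fail("extract_names", "no protein names extracted")
    state.log("extract_names", "ok", ", ".join(state.protein_names))

    state.chosen_protein = state.protein_names[0]
    state.log("choose_protein", "ok", state.chosen_protein)

    try:
        state.protein_sequence = fetch_first_sequence(
            state.chosen_protein, providers.sequence_source
        )
    except ProviderError as exc:
        return fail("fetch_sequence", str(exc))
    state.log("fetch_sequence", "ok", f"{len(state.protein_sequence)} residues")

    try:
        [(raw, trimmed)] = generate_batch(
            clm_model, tokenizer, [state.protein_sequence], gen_config
        )
    except Exception as exc:  # noqa: BLE001
        return fail("generate", str(exc))
    state.raw_smiles = raw
    state.log("generate", "ok", raw)

    state.trimmed_smiles = trimmed
    if not trimmed:
        state.log("trim", "warning", "trimming produced an empty string")
        return state
    state.log("trim", "ok", trimmed)

    try:
        pair = LigandProteinPair(smiles=trimmed, protein_seq=state.protein_sequence)
        encoded = encode_for_rcnn(pair, char_vocab)
        state.predicted_pki = float(predict_pki(rcnn_model, encoded))
    except Exception as exc:  # noqa: BLE001
        return fail("predict", str(exc))
    state.log("predict", "ok", f"pKi={state.predicted_pki:.3f}")
    return state
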