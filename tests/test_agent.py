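"""Prompted extraction, provider contracts, and the orchestrated pipeline."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from agentmol.agent import (
    EXTRACTION_INSTRUCTION,
    InvalidSequenceError,
    MockLlm,
    MockRetriever,
    MockSequenceSource,
    ProviderBundle,
    ProviderError,
    TargetNotFoundError,
    build_extraction_prompt,
    extract_protein_names,
    fetch_first_sequence,
    parse_star_list,
    run_pipeline,
)
from agentmol.clm import GenerationConfig


class TestPrompt:
    def test_instruction_appended_verbatim(self):
        prompt = build_extraction_prompt("EGFR is mutated in lung adenocarcinoma.")
        assert prompt.endswith(EXTRACTION_INSTRUCTION)
        assert prompt.startswith("EGFR is mutated")

    def test_empty_context_gives_bare_instruction(self):
        assert build_extraction_prompt("") == EXTRACTION_INSTRUCTION

    def test_template_contract(self):
        assert "list them using *" in build_extraction_prompt("anything")


class TestParseStarList:
    def test_plain_bullets(self):
        assert parse_star_list("* EGFR\n* KRAS") == ["EGFR", "KRAS"]

    def test_non_bullet_lines_discarded(self):
        assert parse_star_list("Here are proteins:\n* SP100") == ["SP100"]

    def test_no_bullets_is_empty_not_error(self):
        assert parse_star_list("no list here") == []

    @given(st.lists(st.text(alphabet="ABCDEFGH123", min_size=1, max_size=8), max_size=6))
    def test_render_parse_round_trip(self, names):
        rendered = "\n".join(f"* {n}" for n in names)
        assert parse_star_list(rendered) == names


class TestExtraction:
    def test_mock_llm_extraction(self):
        assert extract_protein_names(["any text"], MockLlm("* SP100")) == ["SP100"]

    def test_duplicates_removed_order_kept(self):
        llm = MockLlm("* A\n* A\n* B")
        assert extract_protein_names(["x"], llm) == ["A", "B"]

    def test_provider_failure_wrapped(self):
        def broken(prompt):
            raise ConnectionError("down")

        with pytest.raises(ProviderError):
            extract_protein_names(["x"], broken)


class TestSequenceFetch:
    SOURCE = MockSequenceSource({"SP100": ["mktayiak", "ALTSEQ"], "BAD": ["MK9T"]})

    def test_first_record_uppercased(self):
        assert fetch_first_sequence("SP100", self.SOURCE) == "MKTAYIAK"

    def test_unknown_name(self):
        with pytest.raises(TargetNotFoundError):
            fetch_first_sequence("NOPE", self.SOURCE)

    def test_malformed_sequence(self):
        with pytest.raises(InvalidSequenceError):
            fetch_first_sequence("BAD", self.SOURCE)


def _providers(fixture_corpus, llm_output="* SP100"):
    protein = fixture_corpus[0].protein_seq
    return ProviderBundle(
        llm=MockLlm(llm_output),
        retriever=MockRetriever({"lung cancer protein biomarker": ["abstract one"]}),
        sequence_source=MockSequenceSource({"SP100": [protein]}),
    )


class TestPipeline:
    QUERY = "lung cancer protein biomarker"

    def test_end_to_end_smoke(self, fixture_corpus, tiny_clm, bpe_tokenizer, small_rcnn):
        clm_model, _ = tiny_clm
        rcnn, vocab, _ = small_rcnn
        state = run_pipeline(
            self.QUERY, _providers(fixture_corpus), clm_model, bpe_tokenizer,
            rcnn, vocab, GenerationConfig(temperature=1e-7, seed=0),
        )
        assert not state.failed
        assert state.chosen_protein == "SP100"
        assert state.trimmed_smiles
        assert state.predicted_pki is not None
        stages = [s for s, _, _ in state.trace]
        assert stages == ["retrieve", "extract_names", "choose_protein",
                          "fetch_sequence", "generate", "trim", "predict"]

    def test_empty_retrieval_halts_at_extraction(self, fixture_corpus, tiny_clm,
                                                 bpe_tokenizer, small_rcnn):
        clm_model, _ = tiny_clm
        rcnn, vocab, _ = small_rcnn
        providers = ProviderBundle(
            llm=MockLlm("* SP100"),
            retriever=MockRetriever({}),
            sequence_source=_providers(fixture_corpus).sequence_source,
        )
        state = run_pipeline(self.QUERY, providers, clm_model, bpe_tokenizer, rcnn, vocab)
        assert state.failed
        assert state.trace[-1][:2] == ("extract_names", "failed")
        assert state.protein_sequence == "" and state.predicted_pki is None

    def test_unknown_target_halts_at_fetch(self, fixture_corpus, tiny_clm,
                                           bpe_tokenizer, small_rcnn):
        clm_model, _ = tiny_clm
        rcnn, vocab, _ = small_rcnn
        state = run_pipeline(
            self.QUERY, _providers(fixture_corpus, llm_output="* UNKNOWN"),
            clm_model, bpe_tokenizer, rcnn, vocab,
        )
        assert state.failed
        assert state.trace[-1][:2] == ("fetch_sequence", "failed")
        assert state.raw_smiles == ""

    def test_deterministic_given_inputs(self, fixture_corpus, tiny_clm,
                                        bpe_tokenizer, small_rcnn):
        clm_model, _ = tiny_clm
        rcnn, vocab, _ = small_rcnn
        args = (self.QUERY, _providers(fixture_corpus), clm_model, bpe_tokenizer,
                rcnn, vocab, GenerationConfig(seed=123))
        a = run_pipeline(*args)
        b = run_pipeline(*args)
        assert a.trimmed_smiles == b.trimmed_smiles
        assert a.predicted_pki == b.predicted_pki
        assert a.trace == b.trace
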