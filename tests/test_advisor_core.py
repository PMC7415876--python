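"""Parameter vectors, advisor sets, and the advising argmax."""

import io
import itertools

import pytest

from txadvise.advisor_core import (
    AdvisorSet,
    ParameterVector,
    advise,
    default_vector,
    load_parameter_space,
    read_advisor_set,
    validate_vector,
    write_advisor_set,
)
from txadvise.assemblers import (
    MockAssemblerAdapter,
    random_landscape,
    write_landscape,
)
from txadvise.errors import AdapterError, ValidationError
from txadvise.evaluation import auc
from txadvise.gtf_io import write_gtf
from txadvise.synthetic import ReferenceModel, generate_reference, random_advisor_set


class TestValidateVector:
    def test_default_vector_is_valid(self, small_spec):
        assert validate_vector(small_spec, default_vector(small_spec)) == []

    def test_out_of_bounds_names_the_parameter(self, small_spec):
        v = default_vector(small_spec)
        v.values["a"] = -1
        (violation,) = validate_vector(small_spec, v)
        assert "a" in violation

    def test_extra_parameter_reported(self, small_spec):
        v = default_vector(small_spec)
        v.values["bogus"] = 1
        (violation,) = validate_vector(small_spec, v)
        assert "extra" in violation and "bogus" in violation

    def test_missing_and_wrong_kind(self, small_spec):
        v = ParameterVector({"a": 5, "b": "high", "flip": False})
        msgs = validate_vector(small_spec, v)
        assert any("missing" in m and "mode" in m for m in msgs)
        assert any("b" in m and "real" in m for m in msgs)


class TestAdvisorSetIo:
    def test_round_trip(self, small_spec):
        s = random_advisor_set(small_spec, 5, seed=1)
        buf = io.StringIO()
        write_advisor_set(s, small_spec, buf)
        buf.seek(0)
        back = read_advisor_set(buf, small_spec)
        assert [v.values for v in back] == [v.values for v in s]
        assert [v.provenance for v in back] == [v.provenance for v in s]

    def test_missing_column_names_the_parameter(self, small_spec):
        buf = io.StringIO("provenance\ta\tb\tflip\nx\t1\t1.0\ttrue\n")
        with pytest.raises(ValidationError, match="mode"):
            read_advisor_set(buf, small_spec)

    def test_duplicate_rows_rejected(self, small_spec):
        s = AdvisorSet([default_vector(small_spec)])
        buf = io.StringIO()
        write_advisor_set(s, small_spec, buf)
        text = buf.getvalue()
        dup = text + text.splitlines()[1] + "\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_advisor_set(io.StringIO(dup), small_spec)

    def test_out_of_bounds_row_rejected(self, small_spec):
        buf = io.StringIO(
            "provenance\ta\tb\tflip\tmode\nx\t99\t1.0\ttrue\tfast\n"
        )
        with pytest.raises(ValidationError, match="a"):
            read_advisor_set(buf, small_spec)

    def test_includes_default_detection(self, small_spec):
        s = AdvisorSet([default_vector(small_spec)])
        buf = io.StringIO()
        write_advisor_set(s, small_spec, buf)
        buf.seek(0)
        assert read_advisor_set(buf, small_spec).includes_default


@pytest.fixture
def mock_setup(small_spec, tmp_path):
    """A landscape sample file, reference GTF, and adapter."""
    ref = generate_reference(ReferenceModel(n_genes=450, seed=11))
    ref_path = tmp_path / "ref.gtf"
    write_gtf(ref, ref_path)
    landscape = random_landscape(small_spec, ref, seed=42)
    sample = tmp_path / "sample.yaml"
    write_landscape(landscape, sample, reference_path=ref_path, sample_seed=7)
    adapter = MockAssemblerAdapter(small_spec)
    return small_spec, sample, ref_path, adapter, landscape


class TestAdvise:
    def test_singleton_set_chosen_regardless_of_score(self, mock_setup, tmp_path):
        spec, sample, ref_path, adapter, _ = mock_setup
        v = random_advisor_set(spec, 1, seed=5).vectors[0]
        result = advise(sample, AdvisorSet([v]), adapter, ref_path, tmp_path / "out")
        assert result.chosen_vector == v

    def test_default_first_never_loses(self, mock_setup, tmp_path):
        spec, sample, ref_path, adapter, _ = mock_setup
        vectors = [default_vector(spec)] + random_advisor_set(spec, 4, seed=6).vectors
        s = AdvisorSet(vectors, includes_default=True)
        result = advise(sample, s, adapter, ref_path, tmp_path / "out")
        default_auc = result.per_vector_auc[0]
        assert result.chosen_auc >= default_auc

    def test_chosen_auc_is_rescorable_argmax(self, mock_setup, tmp_path):
        spec, sample, ref_path, adapter, _ = mock_setup
        s = random_advisor_set(spec, 5, seed=8)
        result = advise(sample, s, adapter, ref_path, tmp_path / "out")
        assert result.chosen_auc == max(result.per_vector_auc.values())
        rescored = auc(result.assembly_path, ref_path)
        assert rescored == pytest.approx(result.chosen_auc)

    def test_monotone_under_set_growth(self, mock_setup, tmp_path):
        spec, sample, ref_path, adapter, _ = mock_setup
        vectors = random_advisor_set(spec, 6, seed=9).vectors
        prev = 0.0
        for k in range(1, 7):
            s = AdvisorSet(vectors[:k])
            r = advise(sample, s, adapter, ref_path, tmp_path / f"out{k}")
            assert r.chosen_auc >= prev - 1e-12
            prev = r.chosen_auc

    def test_permutation_invariance_with_distinct_scores(self, mock_setup, tmp_path):
        spec, sample, ref_path, adapter, landscape = mock_setup
        # vectors at increasing distance from the planted optimum -> distinct AUCs
        opt = landscape.optimum
        vectors = []
        for k in range(4):
            values = dict(opt.values)
            values["a"] = max(0, min(10, values["a"] - k))
            vectors.append(ParameterVector(values, provenance=f"d{k}"))
        base = advise(sample, AdvisorSet(vectors), adapter, ref_path,
                      tmp_path / "o0")
        scores = sorted(base.per_vector_auc.values())
        assert len(set(scores)) == len(scores), "need distinct scores for this check"
        for i, perm in enumerate(itertools.islice(
                itertools.permutations(vectors), 1, 4)):
            r = advise(sample, AdvisorSet(list(perm)), adapter, ref_path,
                       tmp_path / f"o{i+1}")
            assert r.chosen_vector == base.chosen_vector

    def test_optimum_in_set_wins(self, mock_setup, tmp_path):
        spec, sample, ref_path, adapter, landscape = mock_setup
        vectors = random_advisor_set(spec, 3, seed=12).vectors
        opt = landscape.optimum
        s = AdvisorSet(vectors + [opt])
        r = advise(sample, s, adapter, ref_path, tmp_path / "out")
        # quality(opt) = 1 strictly dominates the random vectors here
        assert r.chosen_vector == opt
        assert r.chosen_auc == max(r.per_vector_auc.values())

    def test_all_invocations_failing_raises(self, small_spec, tmp_path):
        adapter = MockAssemblerAdapter(small_spec)
        bogus_sample = tmp_path / "bogus.yaml"
        bogus_sample.write_text("kind: something-else\n")
        s = AdvisorSet([default_vector(small_spec)])
        ref = tmp_path / "ref.gtf"
        write_gtf(generate_reference(ReferenceModel(n_genes=5, seed=0)), ref)
        with pytest.raises((AdapterError, ValidationError)):
            advise(bogus_sample, s, adapter, ref, tmp_path / "out")


class TestShippedSpaces:
    @pytest.mark.parametrize("assembler,n_params", [
        ("scallop", 18), ("stringtie", 9)])
    def test_shipped_space_loads_and_validates(self, assembler, n_params):
        from txadvise import shipped_space
        spec = shipped_space(assembler)
        assert len(spec) == n_params
        assert validate_vector(spec, default_vector(spec)) == []
        flags = [p.flag for p in spec]
        assert len(set(flags)) == len(flags)
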