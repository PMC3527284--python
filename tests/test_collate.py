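"""Collation: pooled moments, scan concatenation, best-of selection."""

import math

import numpy as np
import pytest

from simfarm.collate import (
    CollationError,
    best_algorithms,
    concatenate_scan_outputs,
    select_best,
    sensitivity_report,
    summarize_ensemble,
)
from simfarm.fixtures import get_model
from simfarm.optimize import OptimizationResult


def chunk_from_values(values, grid, species):
    """Partial moments (n, grid, species, Σx, Σx²) for a stack of repeats."""
    arr = np.asarray(values, dtype=float)
    return (arr.shape[0], np.asarray(grid, float), list(species),
            arr.sum(axis=0), (arr**2).sum(axis=0))


def test_identical_repeats_have_zero_sd():
    repeat = np.array([[0.0], [2.0], [4.0]])
    summary = summarize_ensemble([chunk_from_values([repeat] * 5, [0, 1, 2], ["A"])])
    np.testing.assert_array_equal(summary.sd, 0.0)
    np.testing.assert_array_equal(summary.mean, repeat)
    assert summary.n_repeats == 5


def test_two_point_sample_sd():
    chunks = [chunk_from_values([[[1.0]], [[3.0]]], [0], ["A"])]
    summary = summarize_ensemble(chunks)
    assert summary.mean[0, 0] == 2.0
    assert summary.sd[0, 0] == pytest.approx(math.sqrt(2.0))


def test_single_repeat_reports_zero_sd():
    summary = summarize_ensemble([chunk_from_values([[[7.0]]], [0], ["A"])])
    assert summary.n_repeats == 1
    assert summary.sd[0, 0] == 0.0


def test_population_divisor_option():
    chunks = [chunk_from_values([[[1.0]], [[3.0]]], [0], ["A"])]
    summary = summarize_ensemble(chunks, sd_divisor="population")
    assert summary.sd[0, 0] == pytest.approx(1.0)


@pytest.mark.parametrize("partition", [[1000], [100] * 10, [10] * 100, [700, 200, 100]])
def test_pooled_moments_match_single_pass_oracle(partition):
    """Any partition of the same repeats gives the direct single-pass
    mean/SD to within 1e-9 relative."""
    rng = np.random.default_rng(0)
    repeats = rng.poisson(10.0, size=(1000, 4, 2)).astype(float)
    grid, species = [0, 1, 2, 3], ["A", "B"]
    chunks, start = [], 0
    for size in partition:
        chunks.append(chunk_from_values(repeats[start:start + size], grid, species))
        start += size
    summary = summarize_ensemble(chunks)
    np.testing.assert_allclose(summary.mean, repeats.mean(axis=0), rtol=1e-9)
    np.testing.assert_allclose(summary.sd, repeats.std(axis=0, ddof=1),
                               rtol=1e-9, atol=1e-12)
    assert np.all(summary.sd >= 0)
    assert np.all(summary.mean <= repeats.max(axis=0) + 1e-12)
    assert np.all(summary.mean >= repeats.min(axis=0) - 1e-12)


def test_mismatched_grid_raises():
    a = chunk_from_values([[[1.0]]], [0], ["A"])
    b = chunk_from_values([[[1.0]]], [1], ["A"])
    with pytest.raises(CollationError, match="chunk 1"):
        summarize_ensemble([a, b])


def write_chunks(tmp_path, rows_per_chunk, header="k\tA\n"):
    paths, i = [], 0
    for c, nrows in enumerate(rows_per_chunk):
        p = tmp_path / f"job_{c}.out"
        lines = [header] + [f"{i + r}\t{(i + r) * 2}\n" for r in range(nrows)]
        p.write_text("".join(lines))
        paths.append(p)
        i += nrows
    return paths


def test_scan_concatenation_in_grid_order(tmp_path):
    paths = write_chunks(tmp_path, [4, 3, 3])
    out = tmp_path / "all.tsv"
    concatenate_scan_outputs(paths, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "k\tA"
    assert len(lines) == 11
    assert [l.split("\t")[0] for l in lines[1:]] == [str(i) for i in range(10)]


def test_scan_concatenation_equals_serial_file(tmp_path):
    paths = write_chunks(tmp_path, [4, 3, 3])
    (tmp_path / "serial").mkdir()
    serial = write_chunks(tmp_path / "serial", [10])
    out_split, out_serial = tmp_path / "split.tsv", tmp_path / "serial.tsv"
    concatenate_scan_outputs(paths, out_split)
    concatenate_scan_outputs(serial, out_serial)
    assert out_split.read_bytes() == out_serial.read_bytes()


def test_scan_missing_chunk_and_bad_header(tmp_path):
    paths = write_chunks(tmp_path, [2, 2])
    with pytest.raises(CollationError, match="missing"):
        concatenate_scan_outputs(paths + [tmp_path / "job_9.out"], tmp_path / "x.tsv")
    paths[1].write_text("WRONG\n1\t2\n")
    with pytest.raises(CollationError, match="header"):
        concatenate_scan_outputs(paths, tmp_path / "y.tsv")


def opt_result(value, params=(1.0,), algorithm="particle_swarm"):
    return OptimizationResult(best_value=value, best_parameters=np.array(params),
                              algorithm=algorithm, evaluations=10,
                              progress_trace=[(0, value)])


def test_select_best_minimize_and_tie_rule():
    results = [opt_result(3.2), opt_result(1.1), opt_result(2.0)]
    assert select_best(results, "minimize") is results[1]
    tie = [opt_result(1.0), opt_result(2.0), opt_result(1.0)]
    assert select_best(tie, "minimize") is tie[0]  # lowest index wins
    assert select_best([tie[1]], "maximize") is tie[1]
    with pytest.raises(CollationError):
        select_best([], "minimize")


def test_select_best_exports_winning_model():
    model = get_model("decay")
    winner, doc = select_best([opt_result(0.5, params=(1.75,))], "minimize",
                              model=model, parameter_names=["k"])
    assert "k = 1.75" in doc
    from simfarm.model import read_native_model
    assert read_native_model(doc).parameters["k"] == 1.75


def test_best_algorithms_tolerance():
    res = {"A": opt_result(1.0), "B": opt_result(1.4), "C": opt_result(2.0)}
    assert best_algorithms(res, "minimize") == {"A"}
    assert best_algorithms(res, "minimize", tolerance=0.5) == {"A", "B"}
    tie = {"A": opt_result(1.0), "B": opt_result(1.0)}
    assert best_algorithms(tie, "minimize") == {"A", "B"}


def test_sensitivity_report_importance():
    results = [opt_result(4.0), opt_result(-1.0),   # p0: max 4, min −1
               opt_result(0.0), opt_result(0.0)]    # p1: insensitive
    report = sensitivity_report(["p0", "p1"], results)
    assert report.importance["p0"] == 5.0
    assert report.importance["p1"] == 0.0
    assert len(report.parameters) == 2
    tsv = report.to_tsv().splitlines()
    assert tsv[0] == "parameter\tmax_value\tmin_value\timportance"
    assert len(tsv) == 3
    with pytest.raises(CollationError, match="expected 2"):
        sensitivity_report(["p0"], results[:1])
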