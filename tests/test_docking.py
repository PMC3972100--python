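"""Docking backend contract and ensemble best-score aggregation."""

import os
import stat

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import albudock as ad
from albudock.docking import STATUS_FAILED, STATUS_OK, DockingResult
from albudock.ligands import LigandRecord
from albudock.receptors import ReceptorStructure, SitePocket


def _ligand(lid="L1"):
    return LigandRecord(lid)


def _receptor(pdb="1N5U", path=None):
    return ReceptorStructure(pdb, file=path, resolution=1.9)


def _site(name="site_II"):
    return SitePocket(name, (10.25, 2.11, -13.75))


@pytest.fixture
def table_backend():
    table = pd.DataFrame(
        {"ligand_id": ["L1", "L2"], "1N5U:site_II": [-9.5, None], "1N5U:site_I": [-7.0, -4.0]}
    )
    return ad.ScoreTableBackend(table)


class TestDock:
    def test_table_lookup(self, table_backend):
        res = ad.dock(_ligand("L1"), _receptor(), _site(), table_backend)
        assert res.status == STATUS_OK
        assert res.score == -9.5

    def test_ligand_absent_gives_failed_not_exception(self, table_backend, caplog):
        with caplog.at_level("WARNING"):
            res = ad.dock(_ligand("L9"), _receptor(), _site(), table_backend)
        assert res.status == STATUS_FAILED
        assert res.score is None
        assert "L9" in caplog.text

    def test_missing_cell_gives_failed(self, table_backend):
        res = ad.dock(_ligand("L2"), _receptor(), _site(), table_backend)
        assert res.status == STATUS_FAILED

    def test_ok_result_requires_finite_score(self):
        with pytest.raises(ValueError, match="finite"):
            DockingResult("L", "1N5U", "site_I", score=None, status=STATUS_OK)


class TestCommandLineBackend:
    """Adapter exercised against a stub engine executable."""

    def _stub(self, tmp_path, body):
        script = tmp_path / "engine"
        script.write_text("#!/bin/sh\n" + body)
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        return str(script)

    def _pdb(self, tmp_path):
        path = tmp_path / "rec.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      0.0   0.0   0.0\nEND\n")
        return path

    def test_parses_affinity_line(self, tmp_path):
        exe = self._stub(tmp_path, "echo 'Affinity: -7.3 (kcal/mol)'\n")
        backend = ad.CommandLineBackend(exe)
        res = ad.dock(_ligand(), _receptor(path=self._pdb(tmp_path)), _site(), backend)
        assert res.status == STATUS_OK
        assert res.score == -7.3

    def test_parses_vina_mode_table(self, tmp_path):
        exe = self._stub(
            tmp_path,
            "printf 'mode |   affinity\\n-----+-----------\\n   1    -6.20   0.0\\n'\n",
        )
        backend = ad.CommandLineBackend(exe)
        res = ad.dock(_ligand(), _receptor(path=self._pdb(tmp_path)), _site(), backend)
        assert res.score == -6.2

    def test_nonzero_exit_gives_failed(self, tmp_path):
        exe = self._stub(tmp_path, "echo boom >&2; exit 3\n")
        backend = ad.CommandLineBackend(exe)
        res = ad.dock(_ligand(), _receptor(path=self._pdb(tmp_path)), _site(), backend)
        assert res.status == STATUS_FAILED
        assert "exit 3" in res.detail

    def test_missing_executable_gives_failed(self, tmp_path):
        backend = ad.CommandLineBackend(str(tmp_path / "nonexistent"))
        res = ad.dock(_ligand(), _receptor(path=self._pdb(tmp_path)), _site(), backend)
        assert res.status == STATUS_FAILED

    def test_box_and_seed_passed_on_command_line(self, tmp_path):
        exe = self._stub(tmp_path, 'echo "$@" > args.txt; echo "Affinity: -1.0"\n')
        backend = ad.CommandLineBackend(exe, seed=7, workdir=tmp_path)
        ad.dock(_ligand(), _receptor(path=self._pdb(tmp_path)), _site(), backend)
        args = (tmp_path / "args.txt").read_text()
        assert "--seed 7" in args
        assert "--center_x 10.25" in args
        assert "--size_x 30.0" in args


def _results(scores, lid="L1", site="site_I"):
    return [
        DockingResult(lid, f"{i}N5U", site, score=s) for i, s in enumerate(scores)
    ]


class TestAggregateBest:
    def test_twenty_predictions_for_full_ensemble(self):
        results = []
        for rec in ad.build_ensemble():
            for site in ad.default_sites():
                results.append(DockingResult("L1", rec.pdb_id, site.site_name, score=-5.0))
        scores, unscored = ad.aggregate_best(results)
        assert scores[0].n_predictions == 20
        assert unscored == []

    def test_single_result(self):
        scores, _ = ad.aggregate_best(_results([-4.2]))
        assert scores[0].best_overall == -4.2
        assert scores[0].n_predictions == 1

    def test_minimum_of_toy_list(self):
        scores, _ = ad.aggregate_best(_results([-3.0, -7.2, -5.1]))
        assert scores[0].best_overall == -7.2

    def test_per_site_minima_and_overall(self):
        results = _results([-3.0, -7.2], site="site_I") + _results(
            [-5.0, -6.0], site="site_II"
        )
        scores, _ = ad.aggregate_best(results)
        s = scores[0]
        assert s.best_site_I == -7.2
        assert s.best_site_II == -6.0
        assert s.best_overall == -7.2
        assert s.best_overall <= s.best_site_I and s.best_overall <= s.best_site_II

    def test_failed_results_excluded(self):
        results = _results([-3.0]) + [
            DockingResult("L1", "9N5U", "site_I", status=STATUS_FAILED)
        ]
        scores, _ = ad.aggregate_best(results)
        assert scores[0].best_overall == -3.0
        assert scores[0].n_predictions == 1

    def test_impute_failed_option(self):
        results = [DockingResult("L1", "1N5U", "site_I", status=STATUS_FAILED)]
        scores, unscored = ad.aggregate_best(results, impute_failed=0.0)
        assert scores[0].best_overall == 0.0
        assert unscored == []

    def test_all_failed_ligand_reported_separately(self):
        results = [DockingResult("L1", "1N5U", "site_I", status=STATUS_FAILED)]
        scores, unscored = ad.aggregate_best(results)
        assert scores == []
        assert unscored == ["L1"]

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            ad.aggregate_best([])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-20, 5), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariance(self, scores, rnd):
        results = _results(scores)
        shuffled = list(results)
        rnd.shuffle(shuffled)
        a, _ = ad.aggregate_best(results)
        b, _ = ad.aggregate_best(shuffled)
        assert a[0].best_overall == b[0].best_overall
        assert a[0].n_predictions == b[0].n_predictions

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-20, 5), min_size=1, max_size=30),
        st.floats(-20, 5),
    )
    def test_adding_a_result_never_raises_best(self, scores, extra):
        before, _ = ad.aggregate_best(_results(scores))
        after, _ = ad.aggregate_best(_results(scores + [extra]))
        assert after[0].best_overall <= before[0].best_overall
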