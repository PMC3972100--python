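"""Pluggable docking backend and ensemble best-score aggregation.

The ensemble protocol docks every compound against site I and site II of
each receptor structure and keeps the best (most negative, kcal/mol)
score over all predictions — 20 per compound for the full ten-structure
ensemble.  Two backends satisfy the contract:

* :class:`ScoreTableBackend` — replays scores from an injected delimited
  table (columns ``<pdbid>:<site>``), so published docking scores or
  synthetic scores drive the downstream model exactly.
* :class:`CommandLineBackend` — adapter around an external docking
  executable with a Vina-style command line, for users who have an
  engine installed.

Score convention throughout: kcal/mol, more negative = more favorable.
"""

from __future__ import annotations

import logging
import math
import re
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

import pandas as pd

from .ligands import LigandRecord
from .receptors import ReceptorStructure, SitePocket

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_FAILED = "failed"


@dataclass
class DockingResult:
    """Score of one (ligand, structure, site) docking prediction."""

    ligand_id: str
    pdb_id: str
    site_name: str
    score: Optional[float] = None  # kcal/mol; more negative = better
    pose: Optional[object] = None
    status: str = STATUS_OK
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status == STATUS_OK and (
            self.score is None or not math.isfinite(self.score)
        ):
            raise ValueError(
                f"{self.ligand_id}/{self.pdb_id}/{self.site_name}: "
                "ok result requires a finite score"
            )


@dataclass
class EnsembleScore:
    """Best-over-ensemble reduction of a ligand's docking predictions."""

    ligand_id: str
    best_overall: float
    best_site_I: Optional[float] = None
    best_site_II: Optional[float] = None
    n_predictions: int = 0


class DockingBackend(Protocol):
    def score(
        self, ligand: LigandRecord, receptor: ReceptorStructure, site: SitePocket
    ) -> float:
        """Return the best pose score (kcal/mol) or raise ``BackendError``."""


class BackendError(RuntimeError):
    """A backend could not produce a score for this (ligand, receptor, site)."""


class ScoreTableBackend:
    """Look up scores in an injected table with ``<pdbid>:<site>`` columns.

    Missing entries (absent ligand, absent column, or NaN cell) raise
    :class:`BackendError`, which :func:`dock` converts to a ``failed``
    result.
    """

    def __init__(self, table: pd.DataFrame):
        if "ligand_id" not in table.columns:
            raise ValueError("score table missing ligand_id column")
        self._table = table.set_index("ligand_id")

    def score(
        self, ligand: LigandRecord, receptor: ReceptorStructure, site: SitePocket
    ) -> float:
        column = f"{receptor.pdb_id}:{site.site_name}"
        if ligand.ligand_id not in self._table.index:
            raise BackendError(f"ligand {ligand.ligand_id!r} not in score table")
        if column not in self._table.columns:
            raise BackendError(f"score table has no column {column!r}")
        value = self._table.at[ligand.ligand_id, column]
        if pd.isna(value):
            raise BackendError(
                f"no score for {ligand.ligand_id!r} in column {column!r}"
            )
        return float(value)


# Patterns that cover Vina-style outputs: the first row of the mode table
# or an explicit "Affinity: -x.y (kcal/mol)" line.
_AFFINITY_RE = re.compile(r"Affinity:\s*(-?\d+(?:\.\d+)?)")
_MODE_ROW_RE = re.compile(r"^\s*1\s+(-?\d+(?:\.\d+)?)\s", re.MULTILINE)


@dataclass
class CommandLineBackend:
    """Adapter around an external docking executable.

    The executable is invoked per (ligand, receptor, site) with the grid
    box centered on the site centroid and sized to the outer box.  A
    fixed seed is passed so reruns agree.  ``flexible`` requests
    side-chain flexibility (``--flex`` with ``flexible_residues``) where
    the engine supports it, standing in for induced-fit protocols.
    """

    executable: str
    exhaustiveness: int = 8
    seed: int = 42
    flexible: bool = False
    flexible_residues: tuple[str, ...] = ()
    extra_args: tuple[str, ...] = ()
    workdir: Optional[Path] = None

    def score(
        self, ligand: LigandRecord, receptor: ReceptorStructure, site: SitePocket
    ) -> float:
        if receptor.file is None:
            raise BackendError(f"{receptor.pdb_id}: no receptor file for engine run")
        ligand_file = getattr(ligand, "file", None)
        cx, cy, cz = receptor.centroid_overrides.get(site.site_name, site.centroid)
        cmd = [
            self.executable,
            "--receptor", str(receptor.file),
            "--ligand", str(ligand_file if ligand_file else ligand.ligand_id),
            "--center_x", str(cx), "--center_y", str(cy), "--center_z", str(cz),
            "--size_x", str(site.outer_box),
            "--size_y", str(site.outer_box),
            "--size_z", str(site.outer_box),
            "--exhaustiveness", str(self.exhaustiveness),
            "--seed", str(self.seed),
        ]
        if self.flexible and self.flexible_residues:
            cmd += ["--flex", ",".join(self.flexible_residues)]
        cmd += list(self.extra_args)
        try:
            proc = subprocess.run(
                cmd, capture_output=True, text=True, cwd=self.workdir, check=False
            )
        except OSError as exc:
            raise BackendError(f"engine unavailable: {exc}") from exc
        if proc.returncode != 0:
            raise BackendError(
                f"engine exit {proc.returncode}: {proc.stderr.strip()[:200]}"
            )
        match = _AFFINITY_RE.search(proc.stdout) or _MODE_ROW_RE.search(proc.stdout)
        if match is None:
            raise BackendError("no affinity found in engine output")
        return float(match.group(1))


def dock(
    ligand: LigandRecord,
    receptor: ReceptorStructure,
    site: SitePocket,
    backend: DockingBackend,
) -> DockingResult:
    """Score one ligand against one site of one receptor structure.

    Backend failures become a ``failed`` result (logged), never an
    exception, so an ensemble run survives individual misses.
    """
    try:
        score = backend.score(ligand, receptor, site)
    except BackendError as exc:
        logger.warning(
            "docking failed for %s/%s/%s: %s",
            ligand.ligand_id, receptor.pdb_id, site.site_name, exc,
        )
        return DockingResult(
            ligand_id=ligand.ligand_id,
            pdb_id=receptor.pdb_id,
            site_name=site.site_name,
            status=STATUS_FAILED,
            detail=str(exc),
        )
    return DockingResult(
        ligand_id=ligand.ligand_id,
        pdb_id=receptor.pdb_id,
        site_name=site.site_name,
        score=score,
    )


def dock_ensemble(
    ligands: Sequence[LigandRecord],
    receptors: Sequence[ReceptorStructure],
    sites: Sequence[SitePocket],
    backend: DockingBackend,
) -> list[DockingResult]:
    """All (ligand x receptor x site) predictions; 20 per compound for
    the full ten-structure two-site ensemble."""
    results = []
    for ligand in ligands:
        for receptor in receptors:
            for site in sites:
                results.append(dock(ligand, receptor, site, backend))
    return results


def aggregate_best(
    results: Iterable[DockingResult],
    *,
    impute_failed: Optional[float] = None,
) -> tuple[list[EnsembleScore], list[str]]:
    """Reduce per-(structure, site) results to one best score per ligand.

    ``best_overall`` is the minimum over all ok predictions; per-site
    minima are kept separately for the site-preference statistic.
    Failed results never contribute to the minima; when ``impute_failed``
    is given, each failed result instead contributes that worst-case
    score.  Ligands with no usable results are returned in the second
    element rather than silently dropped.

    The reduction is permutation-invariant and monotone: adding a result
    can never increase ``best_overall``.
    """
    results = list(results)
    if not results:
        raise ValueError("no docking results to aggregate")
    by_ligand: dict[str, list[DockingResult]] = {}
    for res in results:
        by_ligand.setdefault(res.ligand_id, []).append(res)

    scores: list[EnsembleScore] = []
    unscored: list[str] = []
    for ligand_id, group in by_ligand.items():
        contributing: list[tuple[str, float]] = []
        for res in group:
            if res.status == STATUS_OK:
                contributing.append((res.site_name, res.score))
            elif impute_failed is not None:
                contributing.append((res.site_name, impute_failed))
        if not contributing:
            unscored.append(ligand_id)
            continue
        site_i = [s for name, s in contributing if name == "site_I"]
        site_ii = [s for name, s in contributing if name == "site_II"]
        scores.append(
            EnsembleScore(
                ligand_id=ligand_id,
                best_overall=min(s for _, s in contributing),
                best_site_I=min(site_i) if site_i else None,
                best_site_II=min(site_ii) if site_ii else None,
                n_predictions=len(contributing),
            )
        )
    if unscored:
        logger.warning("%d ligand(s) had no ok docking result: %s",
                       len(unscored), unscored)
    return scores, unscored


def results_to_frame(results: Iterable[DockingResult]) -> pd.DataFrame:
    """Delimited-text-ready view of raw docking results."""
    return pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "pdb_id": r.pdb_id,
                "site": r.site_name,
                "score": r.score,
                "status": r.status,
            }
            for r in results
        ]
    )


def ensemble_to_frame(scores: Iterable[EnsembleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ligand_id": s.ligand_id,
                "xp_best": s.best_overall,
                "best_site_I": s.best_site_I,
                "best_site_II": s.best_site_II,
                "n_predictions": s.n_predictions,
            }
            for s in scores
        ]
    )
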