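"""HSA receptor ensemble and binding-site geometry.

Human serum albumin has two major structurally selective drug sites:
site I (the warfarin site, subdomain IIA) and site II (the
indole/benzodiazepine site, subdomain IIIA).  Site centroids are
expressed in the coordinate frame of the 1.90 Å apo structure 1N5U, to
which every ensemble member is assumed to have been superposed as an
external preprocessing step.  Receptor preparation (hydrogen placement,
His242 double protonation in site I, Arg218 repositioning) is likewise
required preprocessing and is documented, not performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

ALIGNMENT_REFERENCE = "1N5U"

#: Default grid geometry: inner (ligand-center) box 10 A, outer box 30 A.
DEFAULT_INNER_BOX = 10.0
DEFAULT_OUTER_BOX = 30.0

#: Site centroids (Angstrom) in the 1N5U-aligned frame.
SITE_I_CENTROID = (30.5, 13.1, 9.7)
SITE_II_CENTROID = (10.25, 2.11, -13.75)

VALID_SITE_NAMES = ("site_I", "site_II", "extra")

#: The ten best-resolution HSA crystal structures, resolution in Angstrom.
DEFAULT_ENSEMBLE: tuple[tuple[str, float], ...] = (
    ("1N5U", 1.90),
    ("3A73", 2.19),
    ("1E7A", 2.20),
    ("2BXH", 2.25),
    ("2BXP", 2.30),
    ("3JRY", 2.30),
    ("2BXA", 2.35),
    ("1E7B", 2.38),
    ("2XW0", 2.40),
    ("1HK4", 2.40),
)


@dataclass(frozen=True)
class SitePocket:
    """Binding-site geometry: centroid plus inner/outer docking boxes."""

    site_name: str
    centroid: tuple[float, float, float]
    inner_box: float = DEFAULT_INNER_BOX
    outer_box: float = DEFAULT_OUTER_BOX

    def __post_init__(self) -> None:
        base = self.site_name.split(":")[0]
        if base not in VALID_SITE_NAMES:
            raise ValueError(
                f"unknown site name {self.site_name!r}; expected {VALID_SITE_NAMES}"
            )
        if len(self.centroid) != 3:
            raise ValueError("centroid must be an (x, y, z) triple")
        if self.inner_box <= 0 or self.outer_box <= 0:
            raise ValueError("box edges must be positive")
        if self.inner_box > self.outer_box:
            raise ValueError(
                f"inner_box {self.inner_box} exceeds outer_box {self.outer_box}"
            )


@dataclass
class ReceptorStructure:
    """One HSA crystal structure of the docking ensemble."""

    pdb_id: str
    file: Optional[Path] = None
    resolution: float = 0.0
    fatty_acid_retained: bool = False
    alignment_reference: str = ALIGNMENT_REFERENCE
    #: optional per-structure centroid overrides, site_name -> (x, y, z)
    centroid_overrides: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4 or not self.pdb_id[0].isdigit():
            raise ValueError(f"malformed PDB id {self.pdb_id!r}")
        if self.resolution <= 0:
            raise ValueError(f"{self.pdb_id}: resolution must be positive")
        if self.file is not None:
            self.file = Path(self.file)
            if not self.file.exists():
                raise FileNotFoundError(self.file)


def default_sites() -> list[SitePocket]:
    """The two xenobiotic sites with published centroids and boxes."""
    return [
        SitePocket("site_I", SITE_I_CENTROID),
        SitePocket("site_II", SITE_II_CENTROID),
    ]


def load_site_definitions(config: Optional[Path | str] = None) -> list[SitePocket]:
    """Parse a key-value site-definition file into :class:`SitePocket` s.

    The format is line-oriented ``site_name key = value`` text::

        site_I centroid = 30.5 13.1 9.7
        site_I inner_box = 10
        site_I outer_box = 30

    Any omitted value falls back to the defaults (published centroids,
    10 Å inner / 30 Å outer box).  ``config=None`` or an empty file
    yields the two default pockets.
    """
    defaults = {
        "site_I": {"centroid": SITE_I_CENTROID},
        "site_II": {"centroid": SITE_II_CENTROID},
    }
    if config is None:
        return default_sites()
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(path)
    parsed: dict[str, dict] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        try:
            head, value = line.split("=", 1)
            site_name, key = head.split()
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: cannot parse {raw!r}") from exc
        entry = parsed.setdefault(site_name.strip(), {})
        key = key.strip()
        if key == "centroid":
            coords = tuple(float(tok) for tok in value.replace(",", " ").split())
            if len(coords) != 3:
                raise ValueError(f"{path}:{lineno}: centroid needs 3 coordinates")
            entry["centroid"] = coords
        elif key in ("inner_box", "outer_box"):
            entry[key] = float(value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    if not parsed:
        return default_sites()
    pockets = []
    for site_name in ("site_I", "site_II"):
        entry = {**defaults.get(site_name, {}), **parsed.pop(site_name, {})}
        if "centroid" not in entry:
            raise ValueError(f"{site_name}: no centroid given and no default exists")
        pockets.append(SitePocket(site_name, **entry))
    for site_name, entry in parsed.items():  # user-supplied extra pockets
        if "centroid" not in entry:
            raise ValueError(f"{site_name}: extra pocket needs a centroid")
        pockets.append(SitePocket(site_name, **entry))
    return pockets


def save_site_definitions(pockets: Sequence[SitePocket], path: Path | str) -> None:
    """Serialize pockets to the key-value text format (lossless round trip)."""
    lines = []
    for p in pockets:
        cx, cy, cz = p.centroid
        lines.append(f"{p.site_name} centroid = {cx!r} {cy!r} {cz!r}")
        lines.append(f"{p.site_name} inner_box = {p.inner_box!r}")
        lines.append(f"{p.site_name} outer_box = {p.outer_box!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def build_ensemble(
    structure_entries: Optional[Iterable[ReceptorStructure | tuple]] = None,
    *,
    reduced: bool = False,
) -> list[ReceptorStructure]:
    """Assemble the receptor ensemble, sorted by resolution (best first).

    With no entries, returns the default ten-structure manifest (the ten
    best-resolution HSA structures in the PDB at the time the model was
    built).  ``reduced=True`` returns the two-structure model instead:
    2BXP for site I and 1N5U for site II, the latter with its site II
    myristic acid retained — FA occupancy near site II measurably shifts
    drug binding, so the reduced model keeps that fatty acid in the
    receptor file.

    Entries may be :class:`ReceptorStructure` objects or
    ``(pdb_id, resolution)`` / ``(pdb_id, path, resolution, fa_flag)``
    tuples.
    """
    if reduced:
        if structure_entries is not None:
            raise ValueError("reduced model takes no explicit entries")
        return [
            ReceptorStructure("2BXP", resolution=2.30, fatty_acid_retained=False),
            ReceptorStructure("1N5U", resolution=1.90, fatty_acid_retained=True),
        ]
    if structure_entries is None:
        entries = [
            ReceptorStructure(pdb_id, resolution=res) for pdb_id, res in DEFAULT_ENSEMBLE
        ]
    else:
        entries = []
        for item in structure_entries:
            if isinstance(item, ReceptorStructure):
                entries.append(item)
            elif len(item) == 2:
                entries.append(ReceptorStructure(item[0], resolution=item[1]))
            else:
                pdb_id, path, res, fa = item
                entries.append(
                    ReceptorStructure(
                        pdb_id, file=path, resolution=res, fatty_acid_retained=bool(fa)
                    )
                )
    if not entries:
        raise ValueError("empty structure entry list")
    seen: set[str] = set()
    for entry in entries:
        if entry.pdb_id in seen:
            raise ValueError(f"duplicate pdb_id {entry.pdb_id!r}")
        seen.add(entry.pdb_id)
    return sorted(entries, key=lambda e: (e.resolution, e.pdb_id))


def read_manifest(path: Path | str) -> list[ReceptorStructure]:
    """Read an ensemble manifest: tab-delimited pdb_id, path, resolution, fa_flag."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("pdb_id"):
            continue
        pdb_id, file_, res, fa = line.split("\t")
        entries.append(
            (
                pdb_id,
                None if file_ in ("", "-") else file_,
                float(res),
                fa.lower() in ("1", "true", "yes"),
            )
        )
    return build_ensemble(entries)
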