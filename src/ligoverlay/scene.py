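"""Scene assembly: aligned, trimmed entries in named groups, plus emission
of a viewer script and a machine-readable run report.

The scene mirrors what a molecular-graphics session would contain: a single
reference chain (object name ``reference``), user groups of trimmed
ligand-site objects, and a reserved ``map_objects`` group holding the
persisted density fragments.  Each mesh is named ``<object>_mesh`` and is
drawn at the stored contour level (default 1 sigma) carved within the
stored radius (default 1.8 Å) of the ligand.  Entries whose object name is
already present are skipped; one failing entry is logged and does not abort
the run.  Persistence is a re-runnable plain-command viewer script plus
standard-format files (PDB, CCP4) — no binary session, no viewer needed to
build it.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .card import EntrySpec, InputCard
from .density import (
    DensityGrid,
    PIPELINE_MAP_RADIUS,
    extract_fragment,
    read_direct_map,
    read_map_coefficients,
    sigma_scale,
    synthesize_map,
    transform_map,
    write_map,
)
from .structio import (
    Structure,
    load_structure,
    select_chain,
    select_residues,
    write_structure,
)
from .superpose import RigidTransform, apply_transform, superpose_chains
from .xtal import TRUNCATION_RADIUS, symmetry_mates_near, truncate_environment

__all__ = [
    "SceneObject",
    "Scene",
    "SceneError",
    "PALETTE",
    "RESERVED_NAMES",
    "resolve_reference",
    "build_entry",
    "add_entries",
    "emit_viewer_script",
    "write_report",
]

logger = logging.getLogger(__name__)

RESERVED_NAMES = {"reference", "map_objects"}

#: Fixed ordered palette of distinguishable viewer color names; entry colors
#: are drawn from it without replacement (seeded), recycling when exhausted.
PALETTE = [
    "green", "cyan", "magenta", "yellow", "salmon", "slate", "orange",
    "purple", "teal", "wheat", "lightblue", "limegreen", "hotpink",
    "yelloworange", "deepteal", "violet", "sand", "forest", "marine", "olive",
]

DEFAULT_CONTOUR = 1.0  # sigma units
DEFAULT_CARVE = 1.8  # Å


class SceneError(ValueError):
    """Scene assembly or emission failure."""


@dataclass
class SceneObject:
    """One aligned, trimmed entry, optionally with a density fragment."""

    object_name: str
    group: str
    structure: Structure
    color: str
    ligand_chain: str
    ligand_resrange: tuple[int, int]
    map_fragment: Optional[DensityGrid] = None
    mesh_scope: str = "ligand_only"  # or "ligand_plus_environment"
    contour_level: float = DEFAULT_CONTOUR
    carve_radius: float = DEFAULT_CARVE
    transform: RigidTransform = field(default_factory=RigidTransform.identity)
    rmsd: float = 0.0
    n_pairs_initial: int = 0
    n_pairs_final: int = 0
    n_symmetry_mates: int = 0
    n_residues_retained: int = 0
    coord_path: str = ""
    map_path: Optional[str] = None
    map_labels: Optional[tuple[str, str]] = None
    align_chain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.object_name in RESERVED_NAMES:
            raise SceneError(
                f"object name {self.object_name!r} is reserved"
            )
        if self.contour_level <= 0 or self.carve_radius <= 0:
            raise SceneError("contour level and carve radius must be positive")

    @property
    def mesh_name(self) -> str:
        return self.object_name + "_mesh"


@dataclass
class Scene:
    reference: Optional[Structure] = None
    groups: list[tuple[str, list[SceneObject]]] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    _color_pool: list[str] = field(default_factory=list)

    @property
    def objects(self) -> list[SceneObject]:
        return [o for _, members in self.groups for o in members]

    @property
    def object_names(self) -> set[str]:
        return {o.object_name for o in self.objects}

    def group(self, name: str) -> list[SceneObject]:
        for gname, members in self.groups:
            if gname == name:
                return members
        members: list[SceneObject] = []
        self.groups.append((name, members))
        return members

    def next_color(self, rng: random.Random) -> str:
        if not self._color_pool:
            self._color_pool = rng.sample(PALETTE, len(PALETTE))
        return self._color_pool.pop(0)


def _single_chain(s: Structure, chain_id: Optional[str]) -> Structure:
    chain = select_chain(s, chain_id)
    return Structure(
        [chain.copy()], cell=s.cell, space_group=s.space_group, name="reference"
    )


def resolve_reference(
    card: InputCard, existing: Optional[Scene] = None
) -> Structure:
    """The single-chain reference, by precedence: an existing scene's
    reference, the card's ``#REF`` line, else the first entry's structure
    (its align chain or first chain)."""
    if existing is not None and existing.reference is not None:
        return existing.reference
    if card.reference is not None:
        path, chain_id = card.reference
        return _single_chain(load_structure(path), chain_id)
    entries = card.entries
    if entries:
        first = entries[0]
        return _single_chain(load_structure(first.coord_path), first.align_chain)
    raise SceneError("no reference available: card has no #REF and no entries")


def build_entry(
    spec: EntrySpec,
    reference: Structure,
    *,
    truncation_radius: float = TRUNCATION_RADIUS,
    map_radius: float = PIPELINE_MAP_RADIUS,
    mesh_scope: str = "ligand_only",
    contour_level: float = DEFAULT_CONTOUR,
    carve_radius: float = DEFAULT_CARVE,
    color: str = PALETTE[0],
) -> SceneObject:
    """Run the per-entry pipeline: load, superpose onto the reference, add
    symmetry mates, truncate to the ligand environment, and (when a map is
    given) extract/transform/sigma-scale the density fragment."""
    s = load_structure(spec.coord_path)
    ligand = select_residues(s, spec.ligand_chain, spec.ligand_resrange)
    align_chain = select_chain(s, spec.align_chain)
    ref_chain = select_chain(reference, None)
    result = superpose_chains(align_chain, ref_chain)

    mates = symmetry_mates_near(s, ligand, radius=truncation_radius)

    fragment = None
    labels = None
    if spec.map_path is not None:
        if Path(spec.map_path).suffix.lower() == ".mtz":
            coef = read_map_coefficients(spec.map_path)
            labels = coef.labels
            grid = synthesize_map(coef)
        else:
            grid = read_direct_map(spec.map_path)
        frag = extract_fragment(grid, ligand, map_radius)
        fragment = sigma_scale(transform_map(frag, result.transform))

    moved = apply_transform(s, result.transform)
    moved_ligand = select_residues(moved, spec.ligand_chain, spec.ligand_resrange)
    moved_mates = [
        (
            op,
            shift,
            [(cid, _transform_residue(res, result.transform)) for cid, res in copies],
        )
        for op, shift, copies in mates
    ]
    trimmed = truncate_environment(
        moved, moved_ligand, radius=truncation_radius, mates=moved_mates
    )
    trimmed.name = spec.object_name

    return SceneObject(
        object_name=spec.object_name,
        group="",  # set by add_entries
        structure=trimmed,
        color=color,
        ligand_chain=spec.ligand_chain,
        ligand_resrange=spec.ligand_resrange,
        map_fragment=fragment,
        mesh_scope=mesh_scope,
        contour_level=contour_level,
        carve_radius=carve_radius,
        transform=result.transform,
        rmsd=result.rmsd,
        n_pairs_initial=result.n_pairs_initial,
        n_pairs_final=result.n_pairs_final,
        n_symmetry_mates=len(mates),
        n_residues_retained=sum(len(c.residues) for c in trimmed.chains),
        coord_path=str(spec.coord_path),
        map_path=str(spec.map_path) if spec.map_path else None,
        map_labels=labels,
        align_chain=spec.align_chain,
    )


def _transform_residue(res, t: RigidTransform):
    new = res.copy()
    for atom in new.atoms:
        atom.pos = t.rotation @ atom.pos + t.translation
    return new


def add_entries(
    scene: Scene,
    card: InputCard,
    seed: int = 0,
    *,
    truncation_radius: float = TRUNCATION_RADIUS,
    map_radius: float = PIPELINE_MAP_RADIUS,
    mesh_scope: str = "ligand_only",
    contour_level: float = DEFAULT_CONTOUR,
    carve_radius: float = DEFAULT_CARVE,
) -> Scene:
    """Add every card entry to the scene.

    Duplicate object names are skipped with a logged notice; a failing entry
    is recorded and does not abort the run.  Colors are reproducible for a
    fixed seed.
    """
    if scene.reference is None:
        scene.reference = resolve_reference(card, scene)
    rng = random.Random(seed)
    for group_name, members in card.groups:
        target = scene.group(group_name)
        for spec in members:
            record = {
                "object_name": spec.object_name,
                "group": group_name,
                "coord_path": str(spec.coord_path),
                "map_path": str(spec.map_path) if spec.map_path else None,
            }
            if spec.object_name in scene.object_names:
                logger.info("skipping duplicate object %r", spec.object_name)
                record["status"] = "skipped_duplicate"
                scene.records.append(record)
                continue
            try:
                obj = build_entry(
                    spec,
                    scene.reference,
                    truncation_radius=truncation_radius,
                    map_radius=map_radius,
                    mesh_scope=mesh_scope,
                    contour_level=contour_level,
                    carve_radius=carve_radius,
                    color=scene.next_color(rng),
                )
            except Exception as exc:
                logger.error("entry %r failed: %s", spec.object_name, exc)
                record["status"] = "error"
                record["error"] = f"{type(exc).__name__}: {exc}"
                scene.records.append(record)
                continue
            obj.group = group_name
            target.append(obj)
            record.update(
                status="ok",
                align_chain=spec.align_chain,
                transform=obj.transform.matrix4().tolist(),
                rmsd=obj.rmsd,
                n_pairs_initial=obj.n_pairs_initial,
                n_pairs_final=obj.n_pairs_final,
                n_residues_retained=obj.n_residues_retained,
                n_symmetry_mates=obj.n_symmetry_mates,
                map_labels=list(obj.map_labels) if obj.map_labels else None,
                map_sigma=obj.map_fragment.sigma if obj.map_fragment else None,
                map_mean=obj.map_fragment.mean if obj.map_fragment else None,
                color=obj.color,
            )
            scene.records.append(record)
    return scene


def _ligand_selection_expr(obj: SceneObject) -> str:
    lo, hi = obj.ligand_resrange
    resi = str(lo) if lo == hi else f"{lo}-{hi}"
    return f"{obj.object_name} and chain {obj.ligand_chain} and resi {resi}"


def emit_viewer_script(scene: Scene, out_dir: str | Path) -> str:
    """Write per-object PDB/CCP4 files plus a viewer script (``scene.pml``)
    that reconstructs the grouped, colored, meshed scene.  Returns the
    script text."""
    if not scene.objects:
        raise SceneError("empty scene: nothing to emit")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["bg_color white"]
    if scene.reference is not None:
        write_structure(scene.reference, out_dir / "reference.pdb")
        lines.append("load reference.pdb, reference")
        lines.append("color grey80, reference")
    for group_name, members in scene.groups:
        for obj in members:
            pdb_name = f"{obj.object_name}.pdb"
            write_structure(obj.structure, out_dir / pdb_name)
            lines.append(f"load {pdb_name}, {obj.object_name}")
            lines.append(f"color {obj.color}, {obj.object_name} and elem C")
            lines.append(f"group {group_name}, {obj.object_name}")
            if obj.map_fragment is not None:
                map_name = f"{obj.object_name}_map"
                write_map(obj.map_fragment, out_dir / f"{map_name}.ccp4")
                lines.append(f"load {map_name}.ccp4, {map_name}")
                if obj.mesh_scope == "ligand_plus_environment":
                    carve_sel = obj.object_name
                else:
                    carve_sel = _ligand_selection_expr(obj)
                lines.append(
                    f"isomesh {obj.mesh_name}, {map_name}, {obj.contour_level:g}, "
                    f"({carve_sel}), carve={obj.carve_radius:g}"
                )
                lines.append(f"color {obj.color}, {obj.mesh_name}")
                lines.append(f"group {group_name}, {obj.mesh_name}")
                lines.append(f"group map_objects, {map_name}")
    script = "\n".join(lines) + "\n"
    (out_dir / "scene.pml").write_text(script)
    return script


def write_report(scene: Scene, path: str | Path) -> dict:
    """JSON run report: per-entry provenance, transforms, statistics."""
    report = {
        "reference": {
            "chain": scene.reference.chains[0].chain_id
            if scene.reference and scene.reference.chains
            else None,
            "n_residues": len(scene.reference.chains[0].residues)
            if scene.reference and scene.reference.chains
            else 0,
        },
        "groups": [
            {"name": g, "objects": [o.object_name for o in members]}
            for g, members in scene.groups
        ],
        "map_objects": [
            f"{o.object_name}_map" for o in scene.objects if o.map_fragment is not None
        ],
        "entries": scene.records,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    return report
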