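"""End-to-end analysis orchestration.

``run_report`` wires the stages together for one two-protomer complex:
read coordinates, annotate repeats, build the partner (second chain set in
the same file or a crystallographic symmetry mate), run the buried-surface
analysis, per-repeat decomposition, composition, salt bridges and the
biological-vs-crystal call, plus the azimuthal-angle profile and, when an
alignment is supplied, conservation mapping painted into a PDB copy.

The run is deterministic for a given config: the JSON report is written
with sorted keys and no timestamps, and the manifest records the tool
version and a hash of the config, so identical configs produce
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

from . import __version__
from .geometry import DegenerateGeometryError, azimuthal_profile
from .interface import InterfaceParams, analyze_interface
from .sasa import SASAParams
from .seqanalysis import (
    conservation_scores,
    map_alignment_to_structure,
    paint_conservation,
    read_alignment,
)
from .structures import (
    Structure,
    apply_symmetry,
    merge_structures,
    read_repeat_table,
    read_structure,
)

__all__ = ["AnalysisConfig", "ReportError", "run_report"]


class ReportError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class AnalysisConfig:
    """Declarative description of one report run (see ``from_file``)."""

    structure: str
    chains_a: list[str]
    chains_b: list[str] | None = None
    symmetry_op: int | None = None
    lattice_shift: tuple[int, int, int] = (0, 0, 0)
    repeats: str | None = None  # CSV path
    alignment: str | None = None
    alignment_reference: str | None = None
    alignment_chain: str | None = None
    probe_radius: float = 1.4
    n_points: int = 960
    residue_fraction_threshold: float = 0.20
    biological_cutoff: float = 856.0
    salt_bridge_cutoff: float = 4.0
    azimuth: bool = True
    output_dir: str = "cadkit-report"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not os.path.exists(self.structure):
            raise ValueError(f"structure file {self.structure!r} not found")
        if not self.chains_a:
            raise ValueError("chains_a must be non-empty")
        if self.chains_b is None and self.symmetry_op is None:
            raise ValueError("give either chains_b or symmetry_op for the partner")
        if self.alignment and not self.alignment_reference:
            raise ValueError("alignment requires alignment_reference id")
        self.lattice_shift = tuple(self.lattice_shift)  # type: ignore[assignment]

    def config_hash(self) -> str:
        """Hash of the analysis inputs (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_complex(cfg: AnalysisConfig, s: Structure) -> tuple[Structure, set[str], set[str]]:
    if cfg.chains_b is not None:
        return s, set(cfg.chains_a), set(cfg.chains_b)
    mate = apply_symmetry(s, cfg.symmetry_op, cfg.lattice_shift)
    merged = merge_structures([s, mate])
    suffix = f"-s{cfg.symmetry_op}"
    return merged, set(cfg.chains_a), {c + suffix for c in cfg.chains_a}


def run_report(cfg: AnalysisConfig) -> dict:
    """Run the full analysis; returns the report dict and writes the bundle."""
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    written: list[str] = []
    log: list[str] = [f"cadkit {__version__} report, config hash {cfg.config_hash()}"]

    def stage(name: str, fn):
        log.append(f"[{name}] start")
        try:
            out = fn()
        except Exception as exc:
            for path in written:  # remove partial outputs
                if os.path.exists(path):
                    os.remove(path)
            raise ReportError(name, str(exc)) from exc
        log.append(f"[{name}] done")
        return out

    s = stage("read", lambda: read_structure(cfg.structure))
    annotations = (
        stage("annotate", lambda: read_repeat_table(cfg.repeats)) if cfg.repeats else None
    )
    complex_structure, chains_a, chains_b = stage("partner", lambda: _build_complex(cfg, s))
    if annotations and cfg.chains_b is None:
        suffix = f"-s{cfg.symmetry_op}"
        annotations = annotations + [
            dataclasses.replace(a, chain_id=a.chain_id + suffix)
            for a in annotations
            if a.chain_id in chains_a
        ]

    sasa_params = SASAParams(probe_radius=cfg.probe_radius, n_points=cfg.n_points)
    iface_params = InterfaceParams(
        residue_fraction_threshold=cfg.residue_fraction_threshold,
        biological_cutoff=cfg.biological_cutoff,
        salt_bridge_cutoff=cfg.salt_bridge_cutoff,
    )
    log.append(
        f"[interface] probe={cfg.probe_radius} n_points={cfg.n_points} "
        f"threshold={cfg.residue_fraction_threshold} cutoff={cfg.biological_cutoff} "
        f"salt_bridge={cfg.salt_bridge_cutoff}"
    )
    iface = stage(
        "interface",
        lambda: analyze_interface(
            complex_structure, chains_a, chains_b, sasa_params, iface_params, annotations
        ),
    )

    report: dict = {
        "tool": {"name": "cadkit", "version": __version__},
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "interface": {
            "total_area": round(iface.total_area, 3),
            "per_pair_area": {k: round(v, 3) for k, v in sorted(iface.per_pair_area.items())},
            "composition_overall": {k: round(v, 6) for k, v in iface.composition_overall.items()},
            "composition_per_pair": {
                pk: {k: round(v, 6) for k, v in comp.items()}
                for pk, comp in sorted(iface.composition_per_pair.items())
            },
            "salt_bridges": [
                {
                    "residue_a": list(b.residue_a),
                    "residue_b": list(b.residue_b),
                    "atoms": [b.atom_a, b.atom_b],
                    "distance": round(b.distance, 3),
                }
                for b in iface.salt_bridges
            ],
            "classification": iface.classification,
            "n_interface_residues": int(len(iface.interface_residues)),
        },
    }

    if cfg.azimuth and annotations:
        chain_anns = [a for a in annotations if a.chain_id == sorted(chains_a)[0]]
        if len(chain_anns) >= 2:
            try:
                prof = azimuthal_profile(s, chain_anns)
                log.append("[azimuth] done")
            except DegenerateGeometryError as exc:
                # collinear/isotropic repeats: φ undefined, not a failure
                prof = None
                report["azimuth"] = {"undefined": str(exc)}
                log.append(f"[azimuth] undefined: {exc}")
        else:
            prof = None
        if prof is not None:
            report["azimuth"] = {
                "reference": prof.reference_description,
                "entries": [
                    {
                        "repeat": e.repeat_label,
                        "phi": None if e.phi_degrees is None else round(e.phi_degrees, 3),
                        "tilt": round(e.tilt_degrees, 3),
                        "defined": e.defined,
                    }
                    for e in prof.entries
                ],
            }

    if cfg.alignment:
        def _conservation():
            aln = read_alignment(cfg.alignment)
            profile = conservation_scores(aln)
            chain = cfg.alignment_chain or sorted(chains_a)[0]
            mapping = map_alignment_to_structure(
                aln, cfg.alignment_reference, s, chain, profile
            )
            painted = os.path.join(cfg.output_dir, "conservation_painted.pdb")
            paint_conservation(s, mapping, painted)
            written.append(painted)
            return {
                "n_mapped_residues": len(mapping),
                "mean_score": round(
                    float(sum(v[0] for v in mapping.values()) / max(1, len(mapping))), 6
                ),
                "painted_pdb": os.path.basename(painted),
            }

        report["conservation"] = stage("conservation", _conservation)

    per_residue_path = os.path.join(cfg.output_dir, "per_residue.csv")
    iface_table = iface.interface_residues
    iface_table.to_csv(per_residue_path, index=False, float_format="%.4f")
    written.append(per_residue_path)

    report_path = os.path.join(cfg.output_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(report_path)

    log_path = os.path.join(cfg.output_dir, "log.txt")
    with open(log_path, "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report
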