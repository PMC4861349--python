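"""Synthetic targets: conformer pairs under hinge motion plus decoy clouds.

Backbones are self-avoiding C-alpha traces (3.8 Angstrom steps, helical
segments interleaved with smooth coil) so superposition metrics behave like
they do on real chains.  Conformer B is conformer A with the chain after a
hinge residue rigidly rotated; decoys are noisy copies of either conformer,
optionally with a short run of residues deleted.  Every stochastic choice
flows from the SyntheticTargetSpec seed, so generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .assessment import DecoyRecord
from .diversity import ConformerPair
from .metrics import score_pair
from .structure_io import CalphaStructure, ExperimentalMethod, write_structures

__all__ = [
    "SyntheticTargetSpec",
    "generate_backbone",
    "apply_hinge",
    "sample_decoys",
    "write_dataset",
]

STEP = 3.8  # consecutive C-alpha distance, Angstrom
MIN_SEPARATION = 4.0  # non-adjacent C-alpha clash distance
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)
# radius chosen so consecutive helix C-alphas are exactly STEP apart
_HELIX_RADIUS = np.sqrt(STEP**2 - _HELIX_RISE**2) / (2.0 * np.sin(_HELIX_TURN / 2))

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Generative parameters for one synthetic target with ground truth."""

    n_residues: int
    hinge_angle: float  # degrees
    n_decoys_a: int
    n_decoys_b: int
    noise_sigma: float  # Angstrom
    seed: int
    hinge_position: Optional[int] = None  # positional index; default n // 2
    missing_run_prob: float = 0.0
    target_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("n_residues must be >= 20")
        if self.hinge_angle < 0:
            raise ValueError("hinge_angle must be >= 0")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not (0.0 <= self.missing_run_prob <= 1.0):
            raise ValueError("missing_run_prob must be in [0, 1]")
        h = self.hinge
        if not (1 <= h <= self.n_residues - 2):
            raise ValueError("hinge_position must be strictly inside the chain")

    @property
    def hinge(self) -> int:
        return self.n_residues // 2 if self.hinge_position is None else self.hinge_position

    @property
    def tid(self) -> str:
        return self.target_id if self.target_id else f"synt{self.seed}"


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(axis: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    e = np.eye(3)[int(np.argmin(np.abs(axis)))]
    u = _unit(np.cross(axis, e))
    v = np.cross(axis, u)
    phase = rng.uniform(0, 2 * np.pi)
    return np.cos(phase) * u + np.sin(phase) * v, -np.sin(phase) * u + np.cos(phase) * v


def _clashes(point: np.ndarray, coords: list[np.ndarray], skip_last: int) -> bool:
    """True when ``point`` comes within MIN_SEPARATION of any placed C-alpha
    other than the ``skip_last`` most recent (chain-adjacent) ones."""
    if len(coords) <= skip_last:
        return False
    prior = np.asarray(coords[: len(coords) - skip_last])
    return bool((((prior - point) ** 2).sum(axis=1) < MIN_SEPARATION**2).any())


def _try_build(n: int, rng: np.random.Generator) -> Optional[np.ndarray]:
    coords: list[np.ndarray] = [np.zeros(3)]
    direction = _unit(rng.normal(size=3))
    while len(coords) < n:
        helix = rng.random() < 0.5
        seg_len = int(rng.integers(6, 13)) if helix else int(rng.integers(3, 9))
        seg_len = min(seg_len, n - len(coords))
        placed = 0
        for attempt in range(40):
            trial: list[np.ndarray] = []
            if helix:
                axis = _unit(direction)
                u, v = _perp_basis(axis, rng)
                base = coords[-1] - _HELIX_RADIUS * u
                ok = True
                for k in range(1, seg_len + 1):
                    theta = _HELIX_TURN * k
                    p = (base + _HELIX_RISE * k * axis
                         + _HELIX_RADIUS * (np.cos(theta) * u + np.sin(theta) * v))
                    if _clashes(p, coords + trial, skip_last=1):
                        ok = False
                        break
                    trial.append(p)
                if ok:
                    break
            else:
                d = direction.copy()
                ok = True
                for _ in range(seg_len):
                    d = _unit(d + 0.6 * rng.normal(size=3))
                    p = (coords + trial)[-1] + STEP * d
                    if _clashes(p, coords + trial, skip_last=1):
                        ok = False
                        break
                    trial.append(p)
                if ok:
                    direction = d
                    break
        else:
            return None
        coords.extend(trial)
        if helix and len(trial) >= 2:
            direction = _unit(trial[-1] - trial[-2])
        placed += len(trial)
    return np.asarray(coords[:n])


def generate_backbone(
    n_residues: int,
    seed: int,
    structure_id: Optional[str] = None,
    max_restarts: int = 25,
) -> CalphaStructure:
    """Self-avoiding C-alpha trace of ``n_residues`` with 3.8 Angstrom steps.

    Built from interleaved ideal-helix and smoothed-random-coil segments; no
    two non-adjacent C-alphas come closer than 4.0 Angstrom.  Deterministic
    given the seed.

    Raises
    ------
    RuntimeError
        If self-avoidance cannot be satisfied within ``max_restarts``
        rebuild attempts (re-seed in that case).
    """
    if n_residues < 20:
        raise ValueError("n_residues must be >= 20")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = _try_build(n_residues, rng)
        if coords is not None:
            aa = "".join(
                _AA_ALPHABET[i] for i in rng.integers(0, len(_AA_ALPHABET), n_residues)
            )
            return CalphaStructure(
                structure_id=structure_id or f"synth{seed}",
                model_number=1,
                chain_id="A",
                res_nums=np.arange(1, n_residues + 1),
                coords=coords,
                amino_acids=tuple(aa),
                method=ExperimentalMethod.SYNTHETIC,
            )
    raise RuntimeError(
        f"self-avoidance unsatisfiable after {max_restarts} restarts; re-seed"
    )


def _hinge_axis(structure: CalphaStructure, hinge: int) -> np.ndarray:
    """Deterministic axis through the hinge C-alpha, perpendicular to the
    upstream chain direction (unchanged by downstream rotation, so applying
    the same angle twice about it composes)."""
    u = _unit(structure.coords[hinge] - structure.coords[hinge - 1])
    e = np.eye(3)[int(np.argmin(np.abs(u)))]
    return _unit(np.cross(u, e))


def apply_hinge(
    structure: CalphaStructure, hinge_position: int, angle: float
) -> CalphaStructure:
    """Rotate all residues after ``hinge_position`` rigidly about an axis
    through the hinge C-alpha; angle in degrees, 0 is the identity."""
    n = len(structure)
    if not (1 <= hinge_position <= n - 2):
        raise ValueError("hinge_position must be strictly inside the chain")
    axis = _hinge_axis(structure, hinge_position)
    theta = np.deg2rad(angle)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    pivot = structure.coords[hinge_position]
    coords = structure.coords.copy()
    moving = coords[hinge_position + 1 :]
    coords[hinge_position + 1 :] = (moving - pivot) @ R.T + pivot
    return CalphaStructure(
        structure_id=structure.structure_id,
        model_number=structure.model_number + 1,
        chain_id=structure.chain_id,
        res_nums=structure.res_nums.copy(),
        coords=coords,
        amino_acids=structure.amino_acids,
        icodes=structure.icodes,
        method=structure.method,
    )


def _make_decoy(
    source: CalphaStructure,
    decoy_id: str,
    rng: np.random.Generator,
    noise_sigma: float,
    missing_run_prob: float,
    forced_run_length: Optional[int] = None,
) -> CalphaStructure:
    # Per-decoy error scale spans a 4-fold range around noise_sigma so that
    # decoy quality is heterogeneous, as in real decoy populations; with a
    # single homogeneous cloud each reference would pick a different "best"
    # decoy purely by noise-direction chance.
    sigma = noise_sigma * rng.uniform(0.5, 2.0)
    coords = source.coords + rng.normal(scale=sigma, size=source.coords.shape)
    keep = np.ones(len(source), dtype=bool)
    if rng.random() < missing_run_prob:
        run = forced_run_length if forced_run_length else int(rng.integers(1, 9))
        run = min(run, len(source) - 1)
        start = int(rng.integers(0, len(source) - run + 1))
        keep[start : start + run] = False
    idx = np.flatnonzero(keep)
    return CalphaStructure(
        structure_id=decoy_id,
        model_number=1,
        chain_id=source.chain_id,
        res_nums=source.res_nums[idx],
        coords=coords[idx],
        amino_acids=tuple(source.amino_acids[i] for i in idx),
        icodes=tuple(source.icodes[i] for i in idx),
        method=ExperimentalMethod.MODEL,
    )


def sample_decoys(
    spec: SyntheticTargetSpec,
    pair_metrics: tuple[str, ...] = ("rmsd",),
    forced_run_length: Optional[int] = None,
) -> tuple[ConformerPair, list[DecoyRecord]]:
    """Generate a conformer pair and its labelled decoy cloud.

    Conformer A is a fresh backbone, conformer B its hinged copy; the decoy
    cloud holds ``n_decoys_a`` noisy copies of A and ``n_decoys_b`` of B,
    each carrying its true source label.  ``pair_metrics`` selects which
    similarity scores are computed for the conformer pair itself.
    """
    rng = np.random.default_rng(spec.seed)
    backbone_seed = int(rng.integers(0, 2**31 - 1))
    a = generate_backbone(spec.n_residues, backbone_seed, structure_id=spec.tid)
    b = apply_hinge(a, spec.hinge, spec.hinge_angle)
    pair = ConformerPair(
        target_id=spec.tid,
        conformer_a=a,
        conformer_b=b,
        scores_ab=score_pair(a, b, metrics=pair_metrics),
        cause="UNKNOWN",
    )
    decoys: list[DecoyRecord] = []
    for source, label, count in ((a, "A", spec.n_decoys_a), (b, "B", spec.n_decoys_b)):
        for i in range(count):
            did = f"{spec.tid}_d{label.lower()}{i:04d}"
            decoys.append(
                DecoyRecord(
                    decoy_id=did,
                    structure=_make_decoy(
                        source, did, rng, spec.noise_sigma,
                        spec.missing_run_prob, forced_run_length,
                    ),
                    group_label="synthetic",
                    true_source=label,
                )
            )
    return pair, decoys


def write_dataset(
    specs: list[SyntheticTargetSpec], outdir: str | Path
) -> tuple[Path, Path]:
    """Materialise synthetic targets as PDB files plus the two manifest TSVs
    consumed by the assessment pipeline.

    Returns ``(conformers_tsv, decoys_tsv)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conf_rows = ["target_id\tpdb_id\tmodel_number\tchain\tcause\tmethod\tpath"]
    decoy_rows = ["target_id\tdecoy_id\tgroup_label\tchain\tpath"]
    for spec in specs:
        pair, decoys = sample_decoys(spec)
        tdir = outdir / spec.tid
        (tdir / "decoys").mkdir(parents=True, exist_ok=True)
        conf_path = tdir / f"{spec.tid}_conformers.pdb"
        write_structures([pair.conformer_a, pair.conformer_b], conf_path)
        for model_number, conf in ((1, pair.conformer_a), (2, pair.conformer_b)):
            conf_rows.append(
                f"{spec.tid}\t{spec.tid}\t{model_number}\t{conf.chain_id}\t"
                f"UNKNOWN\tSYNTHETIC\t{conf_path}"
            )
        for rec in decoys:
            dpath = tdir / "decoys" / f"{rec.decoy_id}.pdb"
            write_structures([rec.structure], dpath)
            decoy_rows.append(
                f"{spec.tid}\t{rec.decoy_id}\t{rec.group_label}\t"
                f"{rec.structure.chain_id}\t{dpath}"
            )
    conf_tsv = outdir / "conformers.tsv"
    decoy_tsv = outdir / "decoys.tsv"
    conf_tsv.write_text("\n".join(conf_rows) + "\n")
    decoy_tsv.write_text("\n".join(decoy_rows) + "\n")
    return conf_tsv, decoy_tsv
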