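"""Geometry evaluation: rigid superposition, active-site alignment, shells.

The active-site pipeline mirrors how designed structures are screened against
annotated references: globally superpose on the backbone, find for each
annotated site residue the nearest generated residue of identical amino-acid
type, and -- only if every site residue has a one-to-one match -- report the
RMSD over name-paired atoms of the matched residues (success below 1.0 A).
Shell metrics re-superpose on spherical expansions around the site centroid
and report per-radius RMSD and residue-identity fraction.

Structures are accepted either as ``{"coords": Lx3, "identities": L-tokens}``
dicts (C-alpha only) or as :class:`duet.io.ProteinStructure` records; full
backbone selections degrade gracefully to C-alpha when only C-alpha atoms
are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AlignmentResult",
    "ShellMetrics",
    "kabsch_superpose",
    "active_site_align",
    "shell_metrics",
    "select_motif_by_radius",
    "residue_midpoint",
]


@dataclass
class _Residue:
    index: int
    identity: int  # amino-acid token 0..19 (-1 unknown)
    atoms: Dict[str, np.ndarray]

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


def _as_residues(obj) -> List[_Residue]:
    if isinstance(obj, dict) and "coords" in obj:
        coords = np.asarray(obj["coords"], dtype=np.float64)
        ident = np.asarray(obj.get("identities", -np.ones(len(coords))), dtype=np.int64)
        return [
            _Residue(i, int(ident[i]), {"CA": coords[i]}) for i in range(len(coords))
        ]
    if hasattr(obj, "residues"):  # ProteinStructure
        out = []
        for i, res in enumerate(obj.residues):
            out.append(_Residue(i, res.identity, {k: np.asarray(v) for k, v in res.atoms.items()}))
        return out
    raise TypeError("unsupported structure object")


@dataclass
class AlignmentResult:
    rotation: np.ndarray
    translation: np.ndarray
    backbone_rmsd: float
    site_rmsd: Optional[float] = None
    residue_matches: List[Tuple[int, int, float]] = field(default_factory=list)
    identity_fraction: Optional[float] = None
    match_failed: bool = False

    @property
    def success(self) -> bool:
        return (not self.match_failed) and self.site_rmsd is not None and self.site_rmsd < 1.0


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> AlignmentResult:
    """Least-squares rigid transform (proper rotation only) of A onto B.

    Returns rotation R and translation t minimizing ||A @ R.T + t - B||;
    mirror solutions are rejected by construction.  Degenerate (collinear or
    too few) point sets raise.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must be matching N x 3 arrays")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 paired points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A @ R.T + t - B) ** 2, axis=1))))
    return AlignmentResult(rotation=R, translation=t, backbone_rmsd=rmsd)


_BACKBONE = ("N", "CA", "C", "O")


def _paired_backbone(gen: List[_Residue], ref: List[_Residue]):
    a, b = [], []
    for rg, rr in zip(gen, ref):
        names = [n for n in _BACKBONE if n in rg.atoms and n in rr.atoms]
        if not names:
            names = ["CA"] if "CA" in rg.atoms and "CA" in rr.atoms else []
        for n in names:
            a.append(rg.atoms[n])
            b.append(rr.atoms[n])
    return np.asarray(a), np.asarray(b)


def active_site_align(generated, reference, site: Sequence[int]) -> AlignmentResult:
    """Global backbone superposition + typed nearest-residue site matching.

    ``site`` lists annotated residue indices of the reference (>= 2).  After
    globally aligning the generated structure onto the reference, each site
    residue seeks the nearest generated residue of the same amino-acid type
    (minimum distance over any atom pair; ties broken by lower residue
    index; matches are one-to-one).  If any site residue has no same-type
    candidate, the result is flagged ``match_failed`` instead of raising.
    """
    gen = _as_residues(generated)
    ref = _as_residues(reference)
    if len(site) < 2:
        raise ValueError("need at least 2 annotated site residues")
    if len(gen) != len(ref):
        raise ValueError("global superposition requires equal-length structures")
    A, B = _paired_backbone(gen, ref)
    res = kabsch_superpose(A, B)
    moved = [
        _Residue(r.index, r.identity, {k: v @ res.rotation.T + res.translation for k, v in r.atoms.items()})
        for r in gen
    ]
    used: set = set()
    matches: List[Tuple[int, int, float]] = []
    sq_dists: List[float] = []
    for s in site:
        rr = ref[s]
        best: Optional[Tuple[float, int]] = None
        for rg in moved:
            if rg.identity != rr.identity or rg.index in used:
                continue
            dmin = min(
                float(np.linalg.norm(ag - ar))
                for ag in rg.atoms.values()
                for ar in rr.atoms.values()
            )
            if best is None or dmin < best[0] - 1e-12:
                best = (dmin, rg.index)
        if best is None:
            return AlignmentResult(
                rotation=res.rotation,
                translation=res.translation,
                backbone_rmsd=res.backbone_rmsd,
                match_failed=True,
                identity_fraction=len(matches) / len(site),
            )
        used.add(best[1])
        matches.append((s, best[1], best[0]))
        rg = moved[best[1]]
        for name, ar in rr.atoms.items():
            if name in rg.atoms:
                sq_dists.append(float(np.sum((rg.atoms[name] - ar) ** 2)))
    site_rmsd = float(np.sqrt(np.mean(sq_dists)))
    return AlignmentResult(
        rotation=res.rotation,
        translation=res.translation,
        backbone_rmsd=res.backbone_rmsd,
        site_rmsd=site_rmsd,
        residue_matches=matches,
        identity_fraction=1.0,
    )


@dataclass
class ShellMetrics:
    radius: float
    rmsd: Optional[float]
    identity_fraction: Optional[float]
    n_residues: int


def shell_metrics(
    generated, reference, site: Sequence[int], radii: Sequence[float] = tuple(range(1, 19))
) -> List[ShellMetrics]:
    """Per-radius re-superposed RMSD and identity fraction around the site.

    For each radius: select reference residues whose C-alpha lies within the
    radius of the site centroid, re-superpose the generated structure on that
    selection (C-alpha), and report the selection RMSD plus the fraction of
    selected residues whose nearest generated residue (post-alignment) has
    the same identity.  Shells with fewer than 3 residues are undefined.
    """
    gen = _as_residues(generated)
    ref = _as_residues(reference)
    if len(gen) != len(ref):
        raise ValueError("equal-length structures required")
    centroid = np.mean([ref[s].ca for s in site], axis=0)
    ref_ca = np.stack([r.ca for r in ref])
    gen_ca = np.stack([r.ca for r in gen])
    dist = np.linalg.norm(ref_ca - centroid, axis=1)
    out: List[ShellMetrics] = []
    for r in radii:
        sel = np.flatnonzero(dist <= r)
        if len(sel) < 3:
            out.append(ShellMetrics(float(r), None, None, len(sel)))
            continue
        fit = kabsch_superpose(gen_ca[sel], ref_ca[sel])
        moved = gen_ca @ fit.rotation.T + fit.translation
        rmsd = float(np.sqrt(np.mean(np.sum((moved[sel] - ref_ca[sel]) ** 2, axis=1))))
        hits = 0
        for s in sel:
            nearest = int(np.argmin(np.linalg.norm(moved - ref_ca[s], axis=1)))
            hits += int(gen[nearest].identity == ref[s].identity)
        out.append(ShellMetrics(float(r), rmsd, hits / len(sel), len(sel)))
    return out


def select_motif_by_radius(structure, center: np.ndarray, radius: float) -> np.ndarray:
    """Residue indices whose C-alpha lies within ``radius`` of ``center`` (inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    res = _as_residues(structure)
    center = np.asarray(center, dtype=np.float64)
    d = np.array([np.linalg.norm(r.ca - center) for r in res])
    return np.flatnonzero(d <= radius)


def residue_midpoint(structure, resA: int, resB: int) -> np.ndarray:
    """Midpoint of the line connecting two residues' C-alpha atoms."""
    res = _as_residues(structure)
    try:
        return 0.5 * (res[resA].ca + res[resB].ca)
    except IndexError as exc:
        raise ValueError("residue index out of range") from exc
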