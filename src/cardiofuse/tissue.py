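"""Construction of the elongated 3D microtissue lattice.

The engineered tissue is represented as an nx x ny x nz rectangular prism
of cells (default 20 x 20 x 100, five fused 20-cell spheroids end to end).
The propagation axis is z.  The central spheroid may be a pure fibroblast
(CF) block; fibroblast infiltration into the myocyte (CM) region at the
two block faces follows a Gaussian profile of width sigma (in layers),
with the requested number of CFs placed uniformly at random within each
20 x 20 layer.

Each cell couples ohmically to its (up to six) lattice neighbours through
gap junctions: 200 nS for CM-CM, 10 nS for CM-CF, 20 nS for CF-CF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

CM, CF = 0, 1
C_CM, C_CF = 63.0, 6.3  # pF

DEFAULT_GGAP = {(CM, CM): 200.0, (CM, CF): 10.0, (CF, CF): 20.0}

__all__ = [
    "CM", "CF", "C_CM", "C_CF", "DEFAULT_GGAP",
    "BoundaryProfile", "TissueGeometry", "CouplingMap",
    "cf_count_per_layer", "build_elongated_tissue",
    "coupling_conductance", "build_coupling_map",
]


@dataclass(frozen=True)
class BoundaryProfile:
    """Gaussian CF-infiltration profile at the faces of the central block.

    ``z_lo``/``z_hi`` are the 0-based indices of the first and last layer
    of the pure-CF block (the two boundary faces).  ``sigma`` is the
    Gaussian width in layers.  Two interpretations are provided:

    * ``"shoulder"`` (default): CF fraction is 1 inside the block and
      exp(-d^2 / 2 sigma^2) outside, d the distance to the nearest face.
      This matches the drawn density profile (full CF core with Gaussian
      shoulders).
    * ``"literal"``: fraction is the normalised Gaussian
      (1/(sigma sqrt(2 pi))) exp(-((z - z0)/sigma)^2 / 2) about the
      nearest face z0, the printed formula taken at face value.
    """

    z_lo: int = 40
    z_hi: int = 59
    sigma: float = 0.0
    mode: str = "shoulder"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.mode not in ("shoulder", "literal"):
            raise ValueError(f"unknown profile mode {self.mode!r}")
        if self.z_hi < self.z_lo:
            raise ValueError("z_hi must be >= z_lo")


def cf_count_per_layer(z: int, profile: BoundaryProfile, layer_size: int) -> int:
    """Number of CFs in layer z (rounded half-up, clipped to [0, layer_size])."""
    inside = profile.z_lo <= z <= profile.z_hi
    if profile.sigma == 0.0:
        frac = 1.0 if inside else 0.0
    elif profile.mode == "shoulder":
        if inside:
            frac = 1.0
        else:
            d = profile.z_lo - z if z < profile.z_lo else z - profile.z_hi
            frac = float(np.exp(-0.5 * (d / profile.sigma) ** 2))
    elif inside:  # the central spheroid is pure CF in either mode
        frac = 1.0
    else:  # literal printed formula, centred on the nearest block face
        z0 = profile.z_lo if abs(z - profile.z_lo) <= abs(z - profile.z_hi) else profile.z_hi
        frac = float(np.exp(-0.5 * ((z - z0) / profile.sigma) ** 2)
                     / (profile.sigma * np.sqrt(2.0 * np.pi)))
    n = int(np.floor(layer_size * frac + 0.5))
    return min(max(n, 0), layer_size)


@dataclass
class TissueGeometry:
    """Typed 3D lattice.  ``cell_type`` has shape (nx, ny, nz), values CM/CF."""

    cell_type: np.ndarray
    profile: BoundaryProfile | None = None

    @property
    def nx(self) -> int:
        return self.cell_type.shape[0]

    @property
    def ny(self) -> int:
        return self.cell_type.shape[1]

    @property
    def nz(self) -> int:
        return self.cell_type.shape[2]

    @property
    def n_cells(self) -> int:
        return self.cell_type.size

    def flat_types(self) -> np.ndarray:
        """Cell types flattened with index i = x + nx*(y + ny*z)."""
        return np.ascontiguousarray(
            self.cell_type.transpose(2, 1, 0).reshape(-1)).astype(np.uint8)

    def capacitances(self) -> np.ndarray:
        """Per-cell capacitance (pF) in flat order."""
        return np.where(self.flat_types() == CF, C_CF, C_CM)

    def flat_index(self, x, y, z):
        return x + self.nx * (y + self.ny * z)

    def layer_cf_counts(self) -> np.ndarray:
        return (self.cell_type == CF).sum(axis=(0, 1))

    def layer_summary(self):
        """(z, n_CF) table as a structured array, for the CSV summary."""
        counts = self.layer_cf_counts()
        return np.rec.fromarrays([np.arange(self.nz), counts],
                                 names=["z", "n_CF"])

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("cell_type", data=self.cell_type.astype(np.uint8))
            if self.profile is not None:
                for k, v in vars(self.profile).items():
                    f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "TissueGeometry":
        import h5py
        with h5py.File(path, "r") as f:
            ct = f["cell_type"][()]
            attrs = dict(f.attrs)
        prof = BoundaryProfile(**{k: attrs[k].item() if hasattr(attrs[k], "item")
                                  else attrs[k] for k in attrs}) if attrs else None
        return cls(np.asarray(ct), prof)


def build_elongated_tissue(nx: int, ny: int, nz: int,
                           cf_block: tuple[int, int] | None = None,
                           profile: BoundaryProfile | None = None,
                           ) -> TissueGeometry:
    """Build the elongated tissue with a central CF block and Gaussian shoulders.

    ``cf_block = (z_lo, z_hi)`` inclusive 0-based layer range of the pure-CF
    block; ``None`` builds an all-CM tissue.  CF placement within each layer
    is uniform without replacement, deterministic for a given profile seed.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("lattice dimensions must be >= 1")
    ct = np.full((nx, ny, nz), CM, dtype=np.uint8)
    if cf_block is None:
        return TissueGeometry(ct, None)
    z_lo, z_hi = cf_block
    if not (0 <= z_lo <= z_hi < nz):
        raise ValueError("cf_block out of range")
    if profile is None:
        profile = BoundaryProfile(z_lo=z_lo, z_hi=z_hi)
    else:
        profile = replace(profile, z_lo=z_lo, z_hi=z_hi)
    layer_size = nx * ny
    rng = np.random.default_rng(profile.seed)
    for z in range(nz):
        n = cf_count_per_layer(z, profile, layer_size)
        if n == 0:
            continue
        if n >= layer_size:
            ct[:, :, z] = CF
            continue
        flat = rng.choice(layer_size, size=n, replace=False)
        xs, ys = np.unravel_index(flat, (nx, ny))
        ct[xs, ys, z] = CF
    return TissueGeometry(ct, profile)


def coupling_conductance(type_a: int, type_b: int,
                         table: dict | None = None) -> float:
    """Gap-junction conductance (nS) for an (unordered) cell-type pair."""
    table = table or DEFAULT_GGAP
    key = (min(type_a, type_b), max(type_a, type_b))
    if key not in table:
        raise KeyError(f"unknown cell-type pair {type_a!r}, {type_b!r}")
    return table[key]


@dataclass
class CouplingMap:
    """Symmetric nearest-neighbour gap-junction conductances.

    ``pairs`` is an (M, 2) array of flat cell indices (i < k) and
    ``conductances`` the matching nS values.  ``nbr_idx``/``nbr_g`` hold the
    same information as dense (N, 6) neighbour tables (-1 padded) for the
    compiled stepping kernel.
    """

    pairs: np.ndarray
    conductances: np.ndarray
    nbr_idx: np.ndarray
    nbr_g: np.ndarray

    def conductance(self, i: int, k: int) -> float:
        lo, hi = min(i, k), max(i, k)
        mask = (self.pairs[:, 0] == lo) & (self.pairs[:, 1] == hi)
        if not mask.any():
            return 0.0
        return float(self.conductances[mask][0])


def build_coupling_map(geometry: TissueGeometry,
                       table: dict | None = None) -> CouplingMap:
    """One entry per unordered nearest-neighbour pair; no wraparound."""
    table = table or DEFAULT_GGAP
    nx, ny, nz = geometry.nx, geometry.ny, geometry.nz
    types = geometry.flat_types().reshape(nz, ny, nx)  # [z, y, x]
    n = geometry.n_cells
    idx = np.arange(n, dtype=np.int64).reshape(nz, ny, nx)

    pair_i, pair_k, gs = [], [], []
    # contiguous neighbour along each axis
    for axis, sl_a, sl_b in (
        (2, np.s_[:, :, :-1], np.s_[:, :, 1:]),   # x
        (1, np.s_[:, :-1, :], np.s_[:, 1:, :]),   # y
        (0, np.s_[:-1, :, :], np.s_[1:, :, :]),   # z
    ):
        ia, ib = idx[sl_a].ravel(), idx[sl_b].ravel()
        ta, tb = types[sl_a].ravel(), types[sl_b].ravel()
        g = np.empty(ia.shape, dtype=np.float64)
        for (a, b), val in {(CM, CM): coupling_conductance(CM, CM, table),
                            (CM, CF): coupling_conductance(CM, CF, table),
                            (CF, CF): coupling_conductance(CF, CF, table)}.items():
            mask = (np.minimum(ta, tb) == a) & (np.maximum(ta, tb) == b)
            g[mask] = val
        pair_i.append(ia)
        pair_k.append(ib)
        gs.append(g)

    i = np.concatenate(pair_i)
    k = np.concatenate(pair_k)
    g = np.concatenate(gs)
    pairs = np.stack([np.minimum(i, k), np.maximum(i, k)], axis=1)

    # dense neighbour table: one fixed slot per direction (+x,-x,+y,-y,+z,-z)
    nbr_idx = np.full((n, 6), -1, dtype=np.int64)
    nbr_g = np.zeros((n, 6), dtype=np.float64)
    for slot, (ia, ik, gg) in enumerate(zip(pair_i, pair_k, gs)):
        nbr_idx[ia, 2 * slot] = ik
        nbr_g[ia, 2 * slot] = gg
        nbr_idx[ik, 2 * slot + 1] = ia
        nbr_g[ik, 2 * slot + 1] = gg
    return CouplingMap(pairs, g, nbr_idx, nbr_g)
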