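"""Coarse residue-class Ramachandran probability tables.

The packaged grid (``data/rama_tables.tsv``) is a synthetic, analytically
generated stand-in for statistically derived backbone-torsion propensity
maps: each residue class (general / glycine / proline / pre-proline) is a
mixture of truncated anisotropic Gaussian basins centred on the canonical
alpha, beta, polyproline-II and left-handed-alpha regions, evaluated on a
10-degree phi/psi grid and normalised to a maximum density of 1.  Densities
are exactly zero outside 3.5 sigma of every basin, so disallowed regions
are hard-rejected rather than merely penalised.  The generating recipe is
:func:`generate_tables`, which reproduces the shipped file bit-for-bit.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .geometry import wrap_angle

BIN_WIDTH = 10.0
BIN_CENTERS = np.arange(-175.0, 180.0, BIN_WIDTH)  # 36 bins per axis
CLASSES = ("general", "glycine", "proline", "preproline")

# basin mixtures: (phi0, psi0, sigma_phi, sigma_psi, weight); widths are
# generous so the screen rejects only genuinely disallowed torsions (the
# quadrant around (150, -150) stays at exactly zero for non-glycine)
_BASINS = {
    "general": [(-63, -43, 20, 18, 0.35), (-118, 130, 33, 30, 0.30),
                (-65, 145, 22, 24, 0.25), (57, 47, 16, 15, 0.10)],
    "glycine": [(-63, -41, 20, 18, 0.25), (63, 41, 20, 18, 0.25),
                (-100, 140, 35, 35, 0.25), (100, -140, 35, 35, 0.25)],
    "proline": [(-61, -35, 13, 15, 0.5), (-63, 150, 12, 18, 0.5)],
    "preproline": [(-63, -43, 20, 18, 0.30), (-120, 125, 30, 28, 0.35),
                   (-65, 140, 22, 24, 0.30), (55, 40, 16, 15, 0.05)],
}
_TRUNCATION_SIGMA = 3.8


def generate_tables() -> dict:
    """Evaluate the basin mixtures on the grid; max-normalised per class."""
    pp, ps = np.meshgrid(BIN_CENTERS, BIN_CENTERS, indexing="ij")
    tables = {}
    for cls in CLASSES:
        dens = np.zeros_like(pp)
        for phi0, psi0, sp, ssig, w in _BASINS[cls]:
            dphi = wrap_angle(pp - phi0) / sp
            dpsi = wrap_angle(ps - psi0) / ssig
            r2 = dphi ** 2 + dpsi ** 2
            contrib = w * np.exp(-0.5 * r2)
            contrib[r2 > _TRUNCATION_SIGMA ** 2] = 0.0
            dens += contrib
        tables[cls] = dens / dens.max()
    return tables


def write_table_file(path) -> None:
    tables = generate_tables()
    lines = ["phi\tpsi\t" + "\t".join(CLASSES)]
    for i, phi in enumerate(BIN_CENTERS):
        for j, psi in enumerate(BIN_CENTERS):
            vals = "\t".join(f"{tables[c][i, j]:.6g}" for c in CLASSES)
            lines.append(f"{phi:g}\t{psi:g}\t{vals}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class RamachandranTables:
    """Nearest-bin density lookup, scoring and sampling on the packaged grid."""

    def __init__(self, tables: dict | None = None):
        if tables is None:
            tables = self._load_packaged()
        self.tables = tables

    @staticmethod
    def _load_packaged() -> dict:
        ref = resources.files("loopforge").joinpath("data/rama_tables.tsv")
        raw = np.genfromtxt(str(ref), delimiter="\t", names=True)
        tables = {c: np.zeros((len(BIN_CENTERS), len(BIN_CENTERS)))
                  for c in CLASSES}
        pi = np.searchsorted(BIN_CENTERS, raw["phi"])
        si = np.searchsorted(BIN_CENTERS, raw["psi"])
        for c in CLASSES:
            tables[c][pi, si] = raw[c]
        return tables

    @staticmethod
    def residue_class(aa: str, next_aa: str | None = None) -> str:
        if len(aa) != 1 or not aa.isalpha():
            raise ValueError(f"unknown amino-acid code {aa!r}")
        if aa.upper() == "G":
            return "glycine"
        if aa.upper() == "P":
            return "proline"
        if next_aa is not None and next_aa.upper() == "P":
            return "preproline"
        return "general"

    def density(self, phi, psi, aa: str = "A", next_aa: str | None = None):
        """Nearest-bin density for phi/psi in degrees (scalar or array)."""
        cls = self.residue_class(aa, next_aa)
        table = self.tables[cls]
        pi = self._bin_index(phi)
        si = self._bin_index(psi)
        return table[pi, si]

    @staticmethod
    def _bin_index(angle):
        a = wrap_angle(angle)
        idx = np.floor((a + 180.0) / BIN_WIDTH).astype(int)
        return np.clip(idx, 0, len(BIN_CENTERS) - 1)

    def neg_log_density(self, phi, psi, aa: str = "A",
                        next_aa: str | None = None, floor: float = 1e-6):
        d = np.maximum(self.density(phi, psi, aa, next_aa), floor)
        return -np.log(d)

    def sample(self, rng: np.random.Generator, aa: str = "A",
               next_aa: str | None = None, size: int | None = None,
               sharpen: float = 1.0):
        """Draw phi/psi pairs proportional to bin density^sharpen, uniform
        in-bin.  sharpen > 1 concentrates draws near basin modes."""
        cls = self.residue_class(aa, next_aa)
        table = self.tables[cls] ** sharpen
        p = table.ravel() / table.sum()
        n = 1 if size is None else size
        flat = rng.choice(len(p), size=n, p=p)
        pi, si = np.unravel_index(flat, table.shape)
        jitter = rng.uniform(-BIN_WIDTH / 2, BIN_WIDTH / 2, size=(2, n))
        phi = BIN_CENTERS[pi] + jitter[0]
        psi = BIN_CENTERS[si] + jitter[1]
        if size is None:
            return float(phi[0]), float(psi[0])
        return phi, psi


_default: RamachandranTables | None = None


def default_tables() -> RamachandranTables:
    global _default
    if _default is None:
        _default = RamachandranTables()
    return _default
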