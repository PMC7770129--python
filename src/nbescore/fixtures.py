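"""Hand-verified fixture molecules and synthetic statistical data.

The fixture set is a small panel of molecules whose bond multisets,
molecular weights and NBE scores under the shipped default table were
enumerated and summed by hand (twice, independently; see
``docs/fixture_derivations.md``). They are committed as data — not derived
from the parsing code — so parser regressions are caught against frozen
truth. The panel spans the degenerate cases (a bond-free atom, H2) through
drug-like molecules (aspirin, caffeine, ibuprofen, paracetamol).

:func:`generate_property_data` produces synthetic property tables whose
rank correlation with a supplied NBE vector is controlled through a
Gaussian copula. The copula gives an analytic oracle: latent Gaussian
correlation ``r`` yields Spearman correlation ``rho_s = (6/pi) *
arcsin(r/2)``, so tests can compare an empirical rank correlation against
a closed-form target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError

# ((element_a, element_b, order), count) entries; hand enumeration notes in
# docs/fixture_derivations.md. Energies below refer to the shipped default
# table (C-H 413, C-C 347, C=C 614, C#C 839, C-O 358, C=O 745, O-H 467,
# C-N 305, C=N 615, N-H 391, H-H 436 kJ/mol).
BondCount = tuple[tuple[str, str, int], int]


@dataclass(frozen=True)
class FixtureMolecule:
    """One committed fixture: structure plus hand-derived expectations."""

    name: str
    smiles: str
    expected_bonds: tuple[BondCount, ...]
    expected_mw: float           # g/mol, standard average atomic weights
    expected_total_energy: float  # kJ/mol under the default table
    note: str = ""

    @property
    def expected_nbe(self) -> float:
        """Hand total divided by hand MW (kJ/g); 0 for a bond-free atom."""
        return self.expected_total_energy / self.expected_mw

    @property
    def n_bonds(self) -> int:
        return sum(count for _, count in self.expected_bonds)


_FIXTURES: tuple[FixtureMolecule, ...] = (
    FixtureMolecule(
        "neon", "[Ne]", (), 20.180, 0.0,
        "single noble-gas atom: no bonds, NBE is exactly 0",
    ),
    FixtureMolecule(
        "hydrogen", "[H][H]", ((("H", "H", 1), 1),), 2.016, 436.0,
        "one H-H bond (436)",
    ),
    FixtureMolecule(
        "methane", "C", ((("C", "H", 1), 4),), 16.043, 1652.0,
        "4 C-H = 4x413",
    ),
    FixtureMolecule(
        "ethane", "CC",
        ((("C", "C", 1), 1), (("C", "H", 1), 6)),
        30.070, 2825.0, "347 + 6x413",
    ),
    FixtureMolecule(
        "ethene", "C=C",
        ((("C", "C", 2), 1), (("C", "H", 1), 4)),
        28.054, 2266.0, "614 + 4x413",
    ),
    FixtureMolecule(
        "ethyne", "C#C",
        ((("C", "C", 3), 1), (("C", "H", 1), 2)),
        26.038, 1665.0, "839 + 2x413",
    ),
    FixtureMolecule(
        "ethanol", "CCO",
        ((("C", "C", 1), 1), (("C", "O", 1), 1), (("O", "H", 1), 1), (("C", "H", 1), 5)),
        46.069, 3237.0, "347 + 358 + 467 + 5x413",
    ),
    FixtureMolecule(
        "benzene", "c1ccccc1",
        ((("C", "H", 1), 6), (("C", "C", 1), 3), (("C", "C", 2), 3)),
        78.114, 5361.0, "kekulized ring: 6x413 + 3x347 + 3x614",
    ),
    FixtureMolecule(
        "pyridine", "c1ccncc1",
        ((("C", "H", 1), 5), (("C", "C", 1), 2), (("C", "C", 2), 2),
         (("C", "N", 1), 1), (("C", "N", 2), 1)),
        79.102, 4907.0,
        "kekulized ring: 5x413 + 2x347 + 2x614 + 305 + 615; both Kekule "
        "assignments give the same counts",
    ),
    FixtureMolecule(
        "aspirin", "CC(=O)Oc1ccccc1C(=O)O",
        ((("C", "H", 1), 7), (("O", "H", 1), 1), (("C", "C", 1), 5),
         (("C", "C", 2), 3), (("C", "O", 2), 2), (("C", "O", 1), 3)),
        180.159, 9499.0,
        "C9H8O4, 21 bonds: 7x413 + 467 + 5x347 + 3x614 + 2x745 + 3x358",
    ),
    FixtureMolecule(
        "caffeine", "CN1C=NC2=C1C(=O)N(C(=O)N2C)C",
        ((("C", "H", 1), 10), (("C", "N", 1), 10), (("C", "N", 2), 1),
         (("C", "C", 1), 1), (("C", "C", 2), 1), (("C", "O", 2), 2)),
        194.194, 10246.0,
        "C8H10N4O2, 25 bonds: 10x413 + 10x305 + 615 + 347 + 614 + 2x745",
    ),
    FixtureMolecule(
        "ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
        ((("C", "H", 1), 17), (("O", "H", 1), 1), (("C", "C", 1), 10),
         (("C", "C", 2), 3), (("C", "O", 2), 1), (("C", "O", 1), 1)),
        206.285, 13903.0,
        "C13H18O2, 33 bonds: 17x413 + 467 + 10x347 + 3x614 + 745 + 358",
    ),
    FixtureMolecule(
        "paracetamol", "CC(=O)Nc1ccc(O)cc1",
        ((("C", "H", 1), 7), (("N", "H", 1), 1), (("O", "H", 1), 1),
         (("C", "C", 1), 4), (("C", "C", 2), 3), (("C", "O", 2), 1),
         (("C", "N", 1), 2), (("C", "O", 1), 1)),
        151.165, 8692.0,
        "C8H9NO2, 20 bonds: 7x413 + 391 + 467 + 4x347 + 3x614 + 745 + 2x305 + 358",
    ),
)

DRUG_LIKE_FIXTURES = ("aspirin", "caffeine", "ibuprofen", "paracetamol")


def fixture_set() -> tuple[FixtureMolecule, ...]:
    """The committed fixture panel (13 molecules)."""
    return _FIXTURES


def fixture_by_name(name: str) -> FixtureMolecule:
    for fx in _FIXTURES:
        if fx.name == name:
            return fx
    raise KeyError(name)


def spearman_from_gaussian(r: float) -> float:
    """Closed-form Spearman correlation of a bivariate Gaussian copula with
    latent correlation ``r``: (6/pi) * arcsin(r/2)."""
    return 6.0 / math.pi * math.asin(r / 2.0)


def gaussian_from_spearman(rho_s: float) -> float:
    """Inverse of :func:`spearman_from_gaussian`: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class SyntheticPropertyData:
    """Synthetic property table tied to an NBE vector.

    ``frame`` columns: id, nbe, property (rank-correlated with nbe at the
    requested target), group (binary A/B labels), group_value (unit-variance
    normal, group B shifted by ``group_shift``).
    """

    frame: pd.DataFrame
    rank_correlation_target: float
    latent_gaussian_r: float
    group_shift: float
    seed: int


def generate_property_data(
    n: int,
    rank_correlation_target: float,
    group_shift: float,
    seed: int,
    nbe: np.ndarray | None = None,
) -> SyntheticPropertyData:
    """Generate a deterministic synthetic property table.

    The numeric ``property`` column is built through a Gaussian copula on
    the normal scores of the NBE ranks, so its Spearman correlation with
    ``nbe`` approaches ``rank_correlation_target`` as n grows (exactly
    +/-1 at the extremes). ``group_value`` is standard normal with group B
    shifted upward by ``group_shift`` — at shift 0 the two groups share one
    null distribution, which is what type-I-error calibration needs.

    When ``nbe`` is not supplied, a drug-like NBE vector is drawn as
    N(55, 8^2) kJ/g, matching the scale on which real small-molecule panels
    score.
    """
    n = int(n)
    if n < 10:
        raise ArgumentError(f"n must be >= 10, got {n}")
    target = float(rank_correlation_target)
    if not math.isfinite(target) or abs(target) > 1:
        raise ArgumentError(f"rank_correlation_target must be in [-1, 1], got {rank_correlation_target!r}")
    shift = float(group_shift)
    if not math.isfinite(shift):
        raise ArgumentError(f"group_shift must be finite, got {group_shift!r}")

    rng = np.random.default_rng(int(seed))
    if nbe is None:
        nbe = rng.normal(55.0, 8.0, size=n)
    else:
        nbe = np.asarray(nbe, dtype=float)
        if nbe.shape != (n,):
            raise ArgumentError(f"nbe must have shape ({n},), got {nbe.shape}")

    # Normal scores of the NBE ranks: makes the copula target hold for any
    # marginal distribution of the supplied NBE vector.
    ranks = stats.rankdata(nbe, method="average")
    z_nbe = stats.norm.ppf(ranks / (n + 1))
    z_nbe = (z_nbe - z_nbe.mean()) / z_nbe.std()

    r = gaussian_from_spearman(target)
    noise = rng.standard_normal(n)
    z_prop = r * z_nbe + math.sqrt(max(0.0, 1.0 - r * r)) * noise
    # Affine transform only relabels the scale; ranks are untouched.
    prop = 100.0 + 25.0 * z_prop

    labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    labels = labels[rng.permutation(n)]
    group_value = rng.standard_normal(n) + shift * (labels == "B")

    frame = pd.DataFrame(
        {
            "id": [f"mol_{i + 1:05d}" for i in range(n)],
            "nbe": nbe,
            "property": prop,
            "group": labels,
            "group_value": group_value,
        }
    )
    return SyntheticPropertyData(
        frame=frame,
        rank_correlation_target=target,
        latent_gaussian_r=r,
        group_shift=shift,
        seed=int(seed),
    )
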