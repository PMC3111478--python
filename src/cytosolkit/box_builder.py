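"""Model-cytosol box construction.

Converts a table of metabolite concentrations into integer molecule counts
for a cubic box, tops the total metabolite concentration up to a target by
concentration-biased draws from the rare-species list, adds neutralizing
cations (putrescine, Mg²⁺, K⁺) so the box carries zero net charge, and
places every molecule as a buffered sphere by Monte Carlo trial insertion
so the initial configuration has no contacts.

Counting convention: a species at concentration c in a box of volume V is
assigned ``round(c · N_A · V)`` copies; species whose expectation falls
below 0.5 are excluded from automatic inclusion and routed to the rare
list, from which the augmentation step draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AVOGADRO
from .model import SimulationCell

__all__ = [
    "SpeciesEntry",
    "CompositionSpec",
    "PackedConfiguration",
    "PackingError",
    "counts_from_concentrations",
    "augment_with_rare",
    "neutralize",
    "pack_box",
    "build_box",
    "verify_packing",
    "expected_count",
]

# Neutralizing-cation policy of the model cytosol: concentrations in mM and
# net charges in e.  Putrescine is 2+ at the cytosolic pH; Mg²⁺ stands in
# for all divalent monatomic cations; K⁺ absorbs the residual charge.
DEFAULT_ION_POLICY = {
    "putrescine": (28.0, +2.0),
    "Mg2+": (40.0, +2.0),
    "K+": (290.0, +1.0),
}


@dataclass
class SpeciesEntry:
    name: str
    concentration: float  # mol/L
    charge: float = 0.0  # e
    radius: float = 3.0  # packing radius, Å
    abundance: str = "auto"  # auto | rare

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be ≥ 0")
        if self.radius <= 0:
            raise ValueError(f"{self.name}: packing radius must be > 0")
        if self.abundance not in ("auto", "rare"):
            raise ValueError(f"{self.name}: abundance must be auto|rare")


@dataclass
class CompositionSpec:
    """Species table plus box geometry and packing policy."""

    species: list[SpeciesEntry]
    edge: float  # box edge L, Å (cubic)
    target_total_concentration: float | None = None  # mol/L, metabolites
    ion_policy: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ION_POLICY)
    )
    ion_radii: dict[str, float] = field(
        default_factory=lambda: {"putrescine": 3.0, "Mg2+": 1.73, "K+": 2.75}
    )
    buffer: float = 1.0  # Å, added to every pairwise sphere separation
    seed: int = 0
    max_trials: int = 100_000
    boundary: str = "periodic"  # periodic | wall

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("box edge must be positive")
        if self.buffer < 0:
            raise ValueError("buffer must be ≥ 0")
        if self.boundary not in ("periodic", "wall"):
            raise ValueError("boundary must be periodic|wall")

    @property
    def volume_L(self) -> float:
        """Box volume in litres (edge in Å; 1 Å³ = 1e-27 L)."""
        return self.edge**3 * 1e-27

    @classmethod
    def from_table(cls, path, edge: float, **kwargs) -> "CompositionSpec":
        """Load the species table from delimited text
        (columns: name, mM, charge, radius_A, class)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        entries = [
            SpeciesEntry(
                name=str(r["name"]),
                concentration=float(r["mM"]) * 1e-3,
                charge=float(r.get("charge", 0.0)),
                radius=float(r.get("radius_A", 3.0)),
                abundance=str(r.get("class", "auto")),
            )
            for _, r in df.iterrows()
        ]
        return cls(entries, edge, **kwargs)


class PackingError(RuntimeError):
    pass


@dataclass
class PackedConfiguration:
    species: list[str]  # per placed sphere
    centers: np.ndarray  # (N, 3) Å
    radii: np.ndarray  # (N,) Å
    counts: dict[str, int]
    net_charge: float
    cell: SimulationCell

    def counts_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["species", "count"]
        )


def expected_count(concentration: float, volume_L: float) -> float:
    """Expected number of molecules of a species in the box."""
    return concentration * AVOGADRO * volume_L


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def counts_from_concentrations(spec: CompositionSpec):
    """Integer counts per automatically included species + the rare list.

    Species whose expected count is below 0.5 (or that are marked rare) are
    excluded from the automatic counts and returned as the rare list.
    """
    counts: dict[str, int] = {}
    rare: list[SpeciesEntry] = []
    for sp in spec.species:
        exp = expected_count(sp.concentration, spec.volume_L)
        if sp.abundance == "rare" or exp < 0.5:
            rare.append(sp)
            counts[sp.name] = 0
        else:
            counts[sp.name] = _round_half_up(exp)
    return counts, rare


def augment_with_rare(spec: CompositionSpec, counts: dict[str, int],
                      rare: list[SpeciesEntry],
                      rng: np.random.Generator) -> dict[str, int]:
    """Top the total metabolite concentration up to the target.

    Draws one rare species at a time with probability proportional to its
    concentration and increments its count, until the total concentration
    implied by the counts first reaches or exceeds the target.
    """
    counts = dict(counts)
    target = spec.target_total_concentration
    if target is None:
        return counts
    per_molecule = 1.0 / (AVOGADRO * spec.volume_L)  # mol/L per copy
    # compare in molecule-count units with a relative guard so a target that
    # is an exact multiple of one molecule does not overshoot by rounding
    target_n = target / per_molecule * (1.0 - 1e-12)
    total_n = sum(counts.values())
    if total_n >= target_n:
        return counts
    if not rare:
        raise ValueError(
            f"target concentration {target} M unmet at "
            f"{total_n * per_molecule:.4f} M and the rare-species list is empty"
        )
    names = [sp.name for sp in rare]
    conc = np.array([sp.concentration for sp in rare], dtype=float)
    if conc.sum() <= 0:
        raise ValueError("rare species all have zero concentration")
    p = conc / conc.sum()
    while total_n < target_n:
        pick = names[rng.choice(len(names), p=p)]
        counts[pick] = counts.get(pick, 0) + 1
        total_n += 1
    return counts


def neutralize(spec: CompositionSpec, counts: dict[str, int],
               charges: dict[str, float] | None = None) -> dict[str, int]:
    """Ion counts (putrescine, Mg²⁺, K⁺) making total system charge zero.

    Putrescine and Mg²⁺ counts come straight from their policy
    concentrations; K⁺ starts from its policy concentration and is then
    adjusted by the minimal integer change so the box is exactly neutral.
    """
    if charges is None:
        charges = {sp.name: sp.charge for sp in spec.species}
    q_metab = sum(counts.get(name, 0) * q for name, q in charges.items())
    ions: dict[str, int] = {}
    q_ions = 0.0
    for ion, (mM, q) in spec.ion_policy.items():
        n = _round_half_up(expected_count(mM * 1e-3, spec.volume_L))
        ions[ion] = n
        q_ions += n * q
    q_k = spec.ion_policy["K+"][1]
    residual = q_metab + q_ions
    # minimal integer K+ adjustment; residual charge must be an integer
    # multiple of the K+ charge for exact neutrality
    adjust = residual / q_k
    if abs(adjust - round(adjust)) > 1e-9:
        raise ValueError(
            f"residual charge {residual} e is not an integer multiple of the "
            f"K+ charge {q_k} e; exact neutralization impossible"
        )
    ions["K+"] -= int(round(adjust))
    if ions["K+"] < 0:
        raise ValueError(
            "system too positive: neutralization would require negative K+ "
            f"count ({ions['K+']}); no mobile anions are available"
        )
    total_q = q_metab + sum(n * spec.ion_policy[i][1] for i, n in ions.items())
    assert abs(total_q) < 1e-9
    return ions


def _min_image_dist2(delta: np.ndarray, edges: np.ndarray) -> np.ndarray:
    delta = delta - edges * np.round(delta / edges)
    return np.einsum("ij,ij->i", delta, delta)


def pack_box(spec: CompositionSpec, counts: dict[str, int],
             rng: np.random.Generator,
             radii: dict[str, float] | None = None,
             charges: dict[str, float] | None = None) -> PackedConfiguration:
    """Place every molecule as a buffered sphere by Monte Carlo trials.

    Spheres are inserted sequentially in descending radius order; random
    positions are trialled until one clears every previously placed sphere
    by at least ``r_i + r_j + buffer`` under the minimum-image convention
    (or, in ``wall`` mode, also clears the box faces by its own radius).
    """
    if radii is None:
        radii = {sp.name: sp.radius for sp in spec.species}
        radii.update(spec.ion_radii)
    if charges is None:
        charges = {sp.name: sp.charge for sp in spec.species}
        charges.update({k: q for k, (_, q) in spec.ion_policy.items()})
    order = []
    for name, n in counts.items():
        if name not in radii:
            raise KeyError(f"no packing radius for species {name!r}")
        order.extend([name] * int(n))
    order.sort(key=lambda nm: -radii[nm])

    edges = np.full(3, spec.edge)
    centers = np.empty((len(order), 3))
    placed_r = np.empty(len(order))
    for i, name in enumerate(order):
        r = radii[name]
        ok = False
        for _ in range(spec.max_trials):
            pos = rng.uniform(0.0, spec.edge, size=3)
            if spec.boundary == "wall" and (
                np.any(pos < r) or np.any(pos > spec.edge - r)
            ):
                continue
            if i == 0:
                ok = True
                break
            d2 = _min_image_dist2(centers[:i] - pos, edges)
            req = placed_r[:i] + r + spec.buffer
            if np.all(d2 >= req * req):
                ok = True
                break
        if not ok:
            vol_placed = 4.0 / 3.0 * math.pi * float((placed_r[:i] ** 3).sum())
            raise PackingError(
                f"could not place sphere {i} ({name}, r={r} Å) within "
                f"{spec.max_trials} trials; fill fraction so far "
                f"{vol_placed / spec.edge**3:.3f}"
            )
        centers[i] = pos
        placed_r[i] = r

    net_q = sum(counts.get(n, 0) * q for n, q in charges.items())
    return PackedConfiguration(
        species=order,
        centers=centers,
        radii=placed_r,
        counts={k: int(v) for k, v in counts.items()},
        net_charge=float(net_q),
        cell=SimulationCell.cubic(spec.edge),
    )


def build_box(spec: CompositionSpec) -> PackedConfiguration:
    """Full pipeline: counts → rare augmentation → neutralization → packing."""
    rng = np.random.default_rng(spec.seed)
    counts, rare = counts_from_concentrations(spec)
    counts = augment_with_rare(spec, counts, rare, rng)
    ions = neutralize(spec, counts)
    all_counts = {**counts, **ions}
    return pack_box(spec, all_counts, rng)


def verify_packing(config: PackedConfiguration, buffer: float) -> float:
    """Brute-force O(N²) minimum-image validity check.

    Returns the worst (most negative) slack ``d_ij − (r_i + r_j + buffer)``
    over all pairs; a valid packing has slack ≥ 0.
    """
    centers, radii = config.centers, config.radii
    edges = config.cell.edges
    n = len(centers)
    worst = np.inf
    for i in range(n - 1):
        d2 = _min_image_dist2(centers[i + 1:] - centers[i], edges)
        req = radii[i + 1:] + radii[i] + buffer
        worst = min(worst, float(np.min(np.sqrt(d2) - req)))
    return worst
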