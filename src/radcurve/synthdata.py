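"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators, each a pure function of its parameter object and a seed:

* closed 21-point outlines in two or more groups whose mean shapes differ by
  a controlled partial Procrustes distance delta, with isotropic Gaussian
  landmark noise in the raw digitizing frame plus a random similarity
  transform per specimen (camera pose and image scale);
* per-group angle-of-curvature samples (straight radii near 90 degrees,
  curved radii away from it), Gaussian truncated to (0, 180);
* pure-birth ultrametric trees with tip traits evolved by Brownian motion or
  drawn as white noise.

The outline archetypes are checked-in 21-point fixtures built from smooth
closed parametric curves: ``rounded`` mimics the elongate/rounded radial head
of parasagittal taxa and ``reniform`` the compressed, kidney-shaped head of
sprawling taxa.  Group offsets apply a fixed smooth deformation field (a
localized bulge on the side of the outline opposite the fixed landmark),
scaled so the partial Procrustes distance between group mean shapes hits the
requested delta; for the third and later groups the bulge center is rotated
around the outline so the groups separate in different directions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .superimposition import center_and_scale, procrustes_distance
from .tps_io import LandmarkConfiguration, SpecimenRecord, write_tps

__all__ = [
    "OutlineModel",
    "AngleModel",
    "load_archetype",
    "generate_outlines",
    "generate_angles",
    "generate_tree_and_traits",
]


def load_archetype(name: str = "rounded") -> np.ndarray:
    """Load a checked-in 21-point archetype outline ('rounded' or 'reniform')."""
    from .tps_io import read_tps

    with importlib.resources.as_file(
        importlib.resources.files("radcurve.data") / "archetypes.tps"
    ) as path:
        records = read_tps(path)
    by_id = {r.specimen_id: r.configuration.points for r in records}
    if name not in by_id:
        raise ValueError(f"unknown archetype {name!r}; available: {sorted(by_id)}")
    return by_id[name]


@dataclass
class OutlineModel:
    """Parameters for the two-or-more-group outline generator.

    delta is the target partial Procrustes distance between group mean
    shapes (shape units); noise_sd the isotropic per-landmark Gaussian SD in
    the raw frame (the archetype has centroid size 1, so noise is on the
    same scale).  Defaults give clearly separated but non-degenerate groups.
    """

    archetype: str | np.ndarray = "rounded"
    delta: float = 0.08
    noise_sd: float = 0.02
    n_per_group: int = 20
    n_groups: int = 2
    group_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0 or self.noise_sd < 0:
            raise ValueError("delta and noise_sd must be non-negative")
        if self.n_groups < 1 or self.n_per_group < 1:
            raise ValueError("need at least one group and one specimen per group")


@dataclass
class AngleModel:
    """Per-group angle-of-curvature distributions (degrees).

    The sprawled default mean of 90 encodes a straight radius; the
    parasagittal default of 75 is a curved-radius simulation setting.
    """

    means: dict = field(default_factory=lambda: {"sprawled": 90.0, "parasagittal": 75.0})
    sds: dict = field(default_factory=lambda: {"sprawled": 5.0, "parasagittal": 5.0})

    def __post_init__(self):
        for g, m in self.means.items():
            if not 0 < m < 180:
                raise ValueError(f"mean for {g!r} must be in (0, 180)")
        for g, s in self.sds.items():
            if s < 0:
                raise ValueError(f"sd for {g!r} must be non-negative")


def _bulge_field(arch: np.ndarray, center_shift: float = 0.0, width: float = 0.6) -> np.ndarray:
    """Smooth radial bulge opposite the fixed landmark (rotated by center_shift).

    Returns a (k, 2) displacement field with unit Frobenius norm.
    """
    c = arch - arch.mean(axis=0)
    theta = np.arctan2(c[:, 1], c[:, 0])
    theta0 = np.arctan2(-c[0, 1], -c[0, 0]) + center_shift  # opposite landmark 0
    d = np.angle(np.exp(1j * (theta - theta0)))
    g = np.exp(-(d**2) / (2 * width**2))
    radial = c / np.linalg.norm(c, axis=1, keepdims=True)
    field = g[:, None] * radial
    field[0] = 0.0  # the fixed landmark stays put
    return field / np.linalg.norm(field)


def _calibrated_mean(arch: np.ndarray, field: np.ndarray, delta: float) -> np.ndarray:
    """Scale the deformation field so d_PP(archetype, deformed) == delta."""
    from scipy.optimize import brentq

    if delta == 0:
        return arch.copy()

    def f(s):
        return procrustes_distance(arch, arch + s * field) - delta

    hi = 0.1
    while f(hi) < 0 and hi < 1e3:
        hi *= 2
    s_opt = brentq(f, 0.0, hi, xtol=1e-12)
    return arch + s_opt * field


def generate_outlines(
    model: OutlineModel,
    tps_path: str | Path | None = None,
    group_csv: str | Path | None = None,
) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Generate grouped outline specimens; optionally write TPS and group CSV.

    Group 0 sits at the archetype; each further group's mean is the archetype
    deformed along a bulge field (rotated per group) to partial Procrustes
    distance delta.  Specimens add isotropic Gaussian noise and a random
    similarity transform (rotation, translation, scale), which downstream
    superimposition must remove.  Deterministic under the model seed.
    """
    rng = np.random.default_rng(model.seed)
    arch = (
        load_archetype(model.archetype)
        if isinstance(model.archetype, str)
        else np.asarray(model.archetype, dtype=float)
    )
    arch = center_and_scale(arch)
    names = model.group_names or [f"group_{g}" for g in range(model.n_groups)]
    if len(names) != model.n_groups:
        raise ValueError("group_names length must equal n_groups")
    if model.delta > 0.3 or model.noise_sd > 0.1:
        import warnings

        warnings.warn("large delta/noise may produce self-intersecting outlines")
    means = [arch]
    for g in range(1, model.n_groups):
        shift = (g - 1) * 2 * np.pi / max(1, model.n_groups - 1) / 2
        field = _bulge_field(arch, center_shift=shift)
        means.append(_calibrated_mean(arch, field, model.delta))
    records: list[SpecimenRecord] = []
    rows = []
    for g, name in enumerate(names):
        for i in range(model.n_per_group):
            pts = means[g] + rng.normal(0.0, model.noise_sd, size=arch.shape)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(0.5, 2.0)
            shift_xy = rng.uniform(-5, 5, size=2)
            pts = scale * pts @ rot.T + shift_xy
            sid = f"{name}_{i:03d}"
            records.append(
                SpecimenRecord(
                    specimen_id=sid, configuration=LandmarkConfiguration(pts)
                )
            )
            rows.append({"specimen_id": sid, "taxon": sid, "side": "left", "group": name})
    table = pd.DataFrame(rows).set_index("specimen_id")
    if tps_path is not None:
        write_tps(records, tps_path)
    if group_csv is not None:
        table.reset_index().to_csv(group_csv, index=False)
    return records, table


def generate_angles(
    model: AngleModel,
    n_per_group: int = 20,
    seed: int = 0,
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Draw per-group angles from Gaussians truncated to (0, 180) degrees."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in model.means.items():
        sd = model.sds.get(group, 0.0)
        for i in range(n_per_group):
            val = mean if sd == 0 else _trunc_normal(rng, mean, sd)
            rows.append(
                {"specimen_id": f"{group}_{i:03d}", "group": group, "angle_deg": val}
            )
    df = pd.DataFrame(rows)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def _trunc_normal(rng, mean, sd, lo=0.0, hi=180.0) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    raise RuntimeError("truncated normal sampler failed (degenerate parameters)")


class _Node:
    __slots__ = ("children", "length", "name", "value")

    def __init__(self):
        self.children: list[_Node] = []
        self.length = 0.0
        self.name = ""
        self.value = 0.0

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.17g}"
        inner = ",".join(ch.newick() for ch in self.children)
        return f"({inner}):{self.length:.17g}"


def generate_tree_and_traits(
    n_tips: int,
    mode: str = "bm",
    seed: int = 0,
    birth_rate: float = 1.0,
    sigma: float = 1.0,
) -> tuple[str, pd.Series]:
    """Simulate a pure-birth ultrametric tree and tip traits.

    mode='bm' evolves the trait by Brownian motion along branches (variance
    sigma^2 per unit branch length); mode='white' draws i.i.d. normal tip
    values with no tree structure.  Returns (newick string, trait Series
    indexed by tip label).
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    if mode not in ("bm", "white"):
        raise ValueError("mode must be 'bm' or 'white'")
    rng = np.random.default_rng(seed)
    root = _Node()
    # active lineages: (node to split when chosen, birth time)
    active = [(root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.length = t - birth
        for _ in range(2):
            ch = _Node()
            node.children.append(ch)
            active.append((ch, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for i, (node, birth) in enumerate(active):
        node.length = t_end - birth
        node.name = f"t{i + 1}"
    # Brownian motion down the tree
    stack = [root]
    root.value = 0.0
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        for ch in node.children:
            ch.value = node.value + rng.normal(0.0, sigma * np.sqrt(max(ch.length, 0.0)))
            stack.append(ch)
    tips = [nd for nd in order if not nd.children]
    labels = [nd.name for nd in tips]
    if mode == "bm":
        traits = pd.Series({nd.name: nd.value for nd in tips})
    else:
        traits = pd.Series(rng.normal(0.0, sigma, size=len(tips)), index=labels)
    newick = root.newick() + ";"
    return newick, traits.loc[sorted(traits.index, key=lambda s: int(s[1:]))]
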