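"""Synthetic adipocyte scene generator.

Produces registered bright-field z-stack / fluorescence channel pairs with
exact object-level ground truth, emulating the qualitative character of
60x adipocyte imaging: nuclei that are bright in the nuclei channel but only
faintly visible in bright-field, high-contrast lipid droplets (a fraction of
which carry dark interior defects), a weak cytoplasm stain with strong
multiplicative intensity variation, and a 7-plane bright-field stack whose
planes are blurred by plane-dependent defocus. The optics are purely
phenomenological: sufficient for mechanism-level tests, not optically
realistic.

All randomness flows through one seeded generator; a fixed seed reproduces
scenes bit-identically (scene ``i`` of a dataset uses ``spec.seed + i``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import BinaryMask, BrightfieldStack, Channel, ChannelImage

__all__ = ["SceneSpec", "SceneTruth", "SceneExample", "generate_scene",
           "generate_dataset", "split_by_well", "write_dataset", "load_dataset"]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene."""

    size: tuple[int, int] = (128, 128)
    n_nuclei: int = 5
    n_lipids: int = 12
    defect_fraction: float = 0.3
    nucleus_radius_px: tuple[float, float] = (7.0, 11.0)
    lipid_radius_px: tuple[float, float] = (4.0, 9.0)
    brightfield_nucleus_contrast: float = 0.03
    noise_sd: float = 0.01
    n_planes: int = 7
    seed: int = 0

    def __post_init__(self):
        if min(self.nucleus_radius_px) <= 0 or min(self.lipid_radius_px) <= 0:
            raise ValueError("radii must be positive")
        if not 0 <= self.defect_fraction <= 1:
            raise ValueError("defect_fraction must lie in [0, 1]")
        if self.brightfield_nucleus_contrast < 0 or self.noise_sd < 0:
            raise ValueError("contrasts must be >= 0")


@dataclass
class SceneTruth:
    """Exact object-level ground truth of a generated scene."""

    nuclei_mask: BinaryMask
    nuclei_centers: list
    nuclei_labels: np.ndarray
    lipid_labels: np.ndarray
    defective_lipid_ids: list
    cell_labels: np.ndarray


@dataclass
class SceneExample:
    """One registered training example with well metadata."""

    stack: BrightfieldStack
    channels: dict
    truth: SceneTruth
    well: str = "well_00"
    scene_id: int = 0


def _place_centers(rng, shape, n, radii, min_gap, anchors=None, anchor_sd=None,
                   max_tries=400):
    """Rejection-sample non-overlapping object centres (and radii)."""
    h, w = shape
    placed = []  # (r, c, radius)
    for _ in range(n):
        radius = rng.uniform(*radii)
        for attempt in range(max_tries):
            if anchors is not None and len(anchors):
                ar, ac = anchors[rng.integers(len(anchors))]
                r = ar + rng.normal(0, anchor_sd)
                c = ac + rng.normal(0, anchor_sd)
            else:
                r = rng.uniform(0, h)
                c = rng.uniform(0, w)
            margin = radius + 2
            if not (margin <= r < h - margin and margin <= c < w - margin):
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2 >= (radius + prad + min_gap) ** 2
                   for pr, pc, prad in placed):
                placed.append((r, c, radius))
                break
        else:
            raise RuntimeError(
                f"infeasible packing: could not place object {len(placed) + 1} of {n}"
            )
    return placed


def _disc_mask(shape, r0, c0, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def _ellipse_mask(shape, r0, c0, a, b, theta):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr, dc = rr - r0, cc - c0
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_scene(spec: SceneSpec):
    """Generate one scene.

    Returns ``(stack, channels, truth)`` where ``channels`` maps
    ``Channel.NUCLEI/LIPIDS/CYTOPLASM`` to :class:`ChannelImage` and
    ``truth`` carries masks, labels, centres and defect identities.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    shape = (h, w)

    # ------------------------------------------------------------- nuclei
    nuc = _place_centers(rng, shape, spec.n_nuclei, spec.nucleus_radius_px,
                         min_gap=6.0)
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    nuclei_img = np.full(shape, 0.04)
    centers = []
    for k, (r0, c0, radius) in enumerate(nuc, start=1):
        a = radius
        b = radius * rng.uniform(0.7, 1.0)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(shape, r0, c0, a, b, theta)
        nuclei_labels[mask] = k
        nuclei_img[mask] = rng.uniform(0.55, 0.85)
        centers.append((int(round(r0)), int(round(c0))))
    nuclei_img = ndimage.gaussian_filter(nuclei_img, 0.8)

    # ------------------------------------------------------------- lipids
    anchors = [(r, c) for r, c, _ in nuc] or None
    lip = _place_centers(rng, shape, spec.n_lipids, spec.lipid_radius_px,
                         min_gap=3.0, anchors=anchors,
                         anchor_sd=3.0 * max(spec.nucleus_radius_px))
    lipid_labels = np.zeros(shape, dtype=np.int32)
    lipid_img = np.full(shape, 0.03)
    n_defective = int(round(spec.defect_fraction * len(lip)))
    defective_ids = sorted(rng.choice(len(lip), size=n_defective, replace=False) + 1) \
        if n_defective else []
    for k, (r0, c0, radius) in enumerate(lip, start=1):
        mask = _disc_mask(shape, r0, c0, radius)
        lipid_labels[mask] = k
        lipid_img[mask] = rng.uniform(0.65, 0.95)
        if k in defective_ids:
            dent_r = max(2.0, 0.35 * radius)
            max_off = max(0.0, radius - dent_r - 2.0)
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max_off)
            dent = _disc_mask(shape, r0 + off * np.cos(ang), c0 + off * np.sin(ang), dent_r)
            depth = rng.uniform(0.3, 0.45)
            lipid_img[dent & mask] -= depth
    lipid_img = ndimage.gaussian_filter(np.clip(lipid_img, 0, 1), 0.6)

    # ---------------------------------------------------------- cytoplasm
    nuc_mask = nuclei_labels > 0
    dist, (ir, ic) = ndimage.distance_transform_edt(~nuc_mask, return_indices=True)
    cyto_extent = dist <= 2.6 * max(spec.nucleus_radius_px)
    cyto_base = np.where(cyto_extent, 0.16, 0.02)
    variation = ndimage.gaussian_filter(rng.normal(0, 1, shape), 6.0)
    variation = 1.0 + 0.5 * variation / max(np.abs(variation).max(), 1e-9)
    cyto_img = ndimage.gaussian_filter(cyto_base, 2.0) * variation
    cell_labels = np.where(cyto_extent | nuc_mask, nuclei_labels[ir, ic], 0).astype(np.int32)

    # --------------------------------------------------------- bright-field
    texture = 0.5 + 0.04 * ndimage.gaussian_filter(rng.normal(0, 1, shape), 2.0)
    lip_mask = lipid_labels > 0
    eroded = ndimage.binary_erosion(lip_mask, iterations=2)
    rim = lip_mask & ~eroded
    base = texture.copy()
    base[rim] += 0.28                      # bright droplet rims
    base[eroded] -= 0.18                   # dark droplet interiors
    base -= spec.brightfield_nucleus_contrast * (nuclei_img - nuclei_img.min())  # faint nuclei
    focus = (spec.n_planes - 1) / 2.0
    planes = np.empty((spec.n_planes, h, w))
    for p in range(spec.n_planes):
        sigma = 0.6 * abs(p - focus)
        plane = ndimage.gaussian_filter(base, sigma) if sigma > 0 else base
        planes[p] = plane + rng.normal(0, spec.noise_sd, shape)
    planes = np.clip(planes, 0, 1)

    # ------------------------------------------------------------- noise
    def noisy(img):
        return np.clip(img + rng.normal(0, spec.noise_sd, shape), 0, 1)

    channels = {
        Channel.NUCLEI: ChannelImage(noisy(nuclei_img), Channel.NUCLEI),
        Channel.LIPIDS: ChannelImage(noisy(lipid_img), Channel.LIPIDS),
        Channel.CYTOPLASM: ChannelImage(noisy(np.clip(cyto_img, 0, 1)), Channel.CYTOPLASM),
    }
    truth = SceneTruth(
        nuclei_mask=BinaryMask((nuclei_labels > 0).astype(np.uint8)),
        nuclei_centers=centers,
        nuclei_labels=nuclei_labels,
        lipid_labels=lipid_labels,
        defective_lipid_ids=[int(i) for i in defective_ids],
        cell_labels=cell_labels,
    )
    return BrightfieldStack(planes=planes), channels, truth


def generate_dataset(n_scenes: int, spec: SceneSpec | None = None, wells: int = 4):
    """Generate ``n_scenes`` scenes assigned round-robin to ``wells`` wells.

    Returns ``(examples, manifest)`` where examples is a list of
    :class:`SceneExample` and manifest a DataFrame with one row per scene.
    """
    spec = spec or SceneSpec()
    if wells < 3:
        raise ValueError("need at least 3 wells to support grouped splits")
    if n_scenes < wells:
        raise ValueError("n_scenes must be >= wells")
    examples, rows = [], []
    for i in range(n_scenes):
        scene_spec = replace(spec, seed=spec.seed + i)
        stack, channels, truth = generate_scene(scene_spec)
        well = f"well_{i % wells:02d}"
        examples.append(SceneExample(stack=stack, channels=channels, truth=truth,
                                     well=well, scene_id=i))
        rows.append({"scene_id": i, "well": well, "seed": scene_spec.seed,
                     "n_nuclei": spec.n_nuclei, "n_lipids": spec.n_lipids})
    return examples, pd.DataFrame(rows)


def split_by_well(examples, n_train_wells: int, n_val_wells: int):
    """Grouped split: whole wells go to train/validation/test, never shared."""
    wells = sorted({ex.well for ex in examples})
    if n_train_wells + n_val_wells >= len(wells) + 1:
        raise ValueError("not enough wells for the requested split")
    train_wells = set(wells[:n_train_wells])
    val_wells = set(wells[n_train_wells : n_train_wells + n_val_wells])
    train = [ex for ex in examples if ex.well in train_wells]
    val = [ex for ex in examples if ex.well in val_wells]
    test = [ex for ex in examples if ex.well not in train_wells | val_wells]
    return train, val, test


def write_dataset(examples, manifest: pd.DataFrame, out_dir) -> None:
    """Write the TIFF layout consumed by training plus truth and manifest."""
    import json

    from .imaging_io import write_channel, write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ex in examples:
        prefix = f"{ex.well}_s{ex.scene_id:03d}"
        write_stack(ex.stack, out / f"{prefix}_brightfield.tif")
        for ch, img in ex.channels.items():
            write_channel(img, out / f"{prefix}_{ch.value}.tif")
        write_channel(ex.truth.nuclei_mask.pixels.astype(float), out / f"{prefix}_nucmask.tif")
        truth = {
            "nuclei_centers": [list(map(int, c)) for c in ex.truth.nuclei_centers],
            "defective_lipid_ids": ex.truth.defective_lipid_ids,
            "n_nuclei": int(ex.truth.nuclei_labels.max()),
            "n_lipids": int(ex.truth.lipid_labels.max()),
        }
        (out / f"{prefix}_truth.json").write_text(json.dumps(truth, indent=1))
    manifest.to_csv(out / "manifest.csv", index=False)


def load_dataset(data_dir):
    """Load the TIFF layout written by :func:`write_dataset`.

    Object labels are not serialized, so the reloaded truth carries the
    nuclei mask, centres and counts only (sufficient for training and
    image/feature evaluation).
    """
    import json

    from .imaging_io import read_channel, read_stack

    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    examples = []
    for _, row in manifest.iterrows():
        prefix = f"{row['well']}_s{int(row['scene_id']):03d}"
        stack_raw = read_stack(data_dir / f"{prefix}_brightfield.tif")
        stack = BrightfieldStack(planes=stack_raw.planes.astype(np.float64) / 65535.0)
        channels = {
            ch: read_channel(data_dir / f"{prefix}_{ch.value}.tif", channel=ch)
            for ch in Channel
        }
        mask = read_channel(data_dir / f"{prefix}_nucmask.tif", rescale=True).pixels > 0.5
        truth_meta = json.loads((data_dir / f"{prefix}_truth.json").read_text())
        truth = SceneTruth(
            nuclei_mask=BinaryMask(mask.astype(np.uint8)),
            nuclei_centers=[tuple(c) for c in truth_meta["nuclei_centers"]],
            nuclei_labels=np.zeros(mask.shape, dtype=np.int32),
            lipid_labels=np.zeros(mask.shape, dtype=np.int32),
            defective_lipid_ids=truth_meta["defective_lipid_ids"],
            cell_labels=np.zeros(mask.shape, dtype=np.int32),
        )
        examples.append(SceneExample(stack=stack, channels=channels, truth=truth,
                                     well=row["well"], scene_id=int(row["scene_id"])))
    return examples, manifest
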