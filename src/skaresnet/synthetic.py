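"""Synthetic surgical-instrument dataset emulating the SID19 protocol.

SID19 (not publicly deposited) photographs 19 surgical-tool classes,
200 images each, single tool per image on a black light-absorbing
cloth, in two lighting modes (daytime, night with strong lamps), with
open/closed states for forceps and scissors and side views at 30-60
degrees.  Several class pairs are fine-grained: they differ only in
subtle tip geometry (e.g. Appendix forceps have a much rounder fore-end
than Alice forceps).

This module renders parametric tool silhouettes that honor exactly that
protocol contract: class count, per-class counts, states, view-angle
range, near-black background, lighting modes and the fine-grained-pair
structure.  The shape grammar itself (families, handle/jaw/tip
parameters) is invented plumbing - the goal is a dataset whose
difficulty structure mirrors the real one, not photo-realism.

The default rendering resolution is 512 px (the native 3456 px is
available via ``image_size``); preprocessing downscales to <= 448 px
anyway.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

SID19_CLASS_NAMES = (
    "Abdominal wall hook",
    "Alice forceps",
    "Appendix forceps",
    "Attraction tube",
    "Bending plate",
    "Curved tip surgical scissors",
    "Dressing tweezers",
    "Elbow hemostatic forceps",
    "Integrated tissue scissors",
    "Intestinal tract",
    "Needle holder",
    "No.4 tool holder",
    "Oval forceps",
    "Pad towel forceps",
    "S deep pull hook",
    "Straight hemostatic forceps",
    "Straight tip surgical scissors",
    "Tissue hook",
    "Tissue tweezers",
)

LIGHTING_MODES = ("day", "night-with-lamp")
STATES = ("open", "closed")


@dataclass
class ClassSpec:
    """Parametric shape description of one tool class."""

    name: str
    family: str                      # forceps | scissors | hook | other
    handle_len: float = 0.72         # fraction of canvas
    handle_width: float = 0.035
    jaw_len: float = 0.22
    jaw_curve: float = 0.0           # lateral bend of the jaw tip (canvas units)
    tip_roundness: float = 0.0       # radius of the rounded fore-end
    serration: int = 0               # tooth count drawn at the tip
    rings: bool = False              # finger rings at the handle end
    open_angle: float = 18.0         # jaw half-angle in the open state
    fine_grained_partner: str | None = None

    @property
    def has_state(self) -> bool:
        return self.family in ("forceps", "scissors")


def default_class_specs() -> dict:
    """The 19 default classes; fine-grained partners differ only in
    designated tip parameters."""
    s = {}

    def add(name, family, **kw):
        s[name] = ClassSpec(name=name, family=family, **kw)

    add("Abdominal wall hook", "hook", handle_len=0.62, handle_width=0.05,
        jaw_len=0.26, jaw_curve=0.16)
    add("Alice forceps", "forceps", jaw_len=0.20, tip_roundness=0.012,
        serration=3, rings=True, fine_grained_partner="Appendix forceps")
    add("Appendix forceps", "forceps", jaw_len=0.20, tip_roundness=0.05,
        serration=3, rings=True, fine_grained_partner="Alice forceps")
    add("Attraction tube", "other", handle_len=0.85, handle_width=0.030,
        jaw_len=0.0)
    add("Bending plate", "other", handle_len=0.66, handle_width=0.085,
        jaw_len=0.0, jaw_curve=0.10)
    add("Curved tip surgical scissors", "scissors", jaw_len=0.24,
        jaw_curve=0.055, rings=True,
        fine_grained_partner="Straight tip surgical scissors")
    add("Dressing tweezers", "forceps", handle_len=0.6, handle_width=0.022,
        jaw_len=0.26, open_angle=7.0)
    add("Elbow hemostatic forceps", "forceps", jaw_len=0.22, jaw_curve=0.06,
        rings=True, fine_grained_partner="Straight hemostatic forceps")
    add("Integrated tissue scissors", "scissors", jaw_len=0.30,
        handle_width=0.045, rings=True)
    add("Intestinal tract", "forceps", handle_len=0.64, handle_width=0.055,
        jaw_len=0.30, open_angle=10.0, rings=True)
    add("Needle holder", "forceps", jaw_len=0.12, handle_width=0.04,
        serration=5, rings=True)
    add("No.4 tool holder", "other", handle_len=0.78, handle_width=0.045,
        jaw_len=0.0)
    add("Oval forceps", "forceps", jaw_len=0.24, tip_roundness=0.07,
        open_angle=12.0, rings=True)
    add("Pad towel forceps", "forceps", jaw_len=0.18, jaw_curve=0.09,
        tip_roundness=0.02, rings=True)
    add("S deep pull hook", "hook", handle_len=0.58, handle_width=0.06,
        jaw_len=0.30, jaw_curve=-0.14)
    add("Straight hemostatic forceps", "forceps", jaw_len=0.22, jaw_curve=0.0,
        rings=True, fine_grained_partner="Elbow hemostatic forceps")
    add("Straight tip surgical scissors", "scissors", jaw_len=0.24,
        jaw_curve=0.0, rings=True,
        fine_grained_partner="Curved tip surgical scissors")
    add("Tissue hook", "hook", handle_len=0.66, handle_width=0.035,
        jaw_len=0.20, jaw_curve=0.11)
    add("Tissue tweezers", "forceps", handle_len=0.68, handle_width=0.024,
        jaw_len=0.22, open_angle=8.0)
    return s


@dataclass
class DatasetManifest:
    classes: tuple = SID19_CLASS_NAMES
    per_class: int = 200
    image_size: int = 512
    side_view_angle_range: tuple = (30.0, 60.0)
    lighting_modes: tuple = LIGHTING_MODES
    seed: int = 0
    channel_mean: tuple | None = None   # filled from the training split
    channel_std: tuple | None = None

    def __post_init__(self):
        self.classes = tuple(self.classes)
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        lo, hi = self.side_view_angle_range
        if not (0.0 <= lo <= hi <= 90.0):
            raise ValueError("side_view_angle_range must lie within [0, 90]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        for key in ("classes", "side_view_angle_range", "lighting_modes",
                    "channel_mean", "channel_std"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Pose:
    state: str = "closed"
    angle: float = 45.0       # side-view angle, degrees
    rotation: float = 0.0     # in-plane rotation, degrees
    lighting: str = "day"

    def validate(self, manifest: DatasetManifest | None = None) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if self.lighting not in LIGHTING_MODES:
            raise ValueError(f"lighting must be one of {LIGHTING_MODES}")
        rng_lo, rng_hi = (manifest.side_view_angle_range if manifest
                          else (0.0, 90.0))
        if not (rng_lo <= self.angle <= rng_hi):
            raise ValueError(
                f"side-view angle {self.angle} outside [{rng_lo}, {rng_hi}]"
            )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _transform(points, rotation_deg: float, foreshorten: float, size: int):
    """Canonical [-0.5, 0.5]^2 coords -> pixel coords with planar rotation
    and side-view (y-axis) foreshortening."""
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)
    out = []
    for x, y in points:
        y = y * foreshorten
        xr, yr = c * x - s * y, s * x + c * y
        out.append(((xr + 0.5) * size, (yr + 0.5) * size))
    return out


def _tool_strokes(spec: ClassSpec, state: str):
    """Stroke list (kind, payload) in canonical coordinates, tool axis on x.

    Returns (strokes, tip_box) where tip_box is the canonical bounding box
    of the fore-end region that fine-grained partners may differ in.
    """
    strokes = []
    hl, hw = spec.handle_len, spec.handle_width
    x0 = -hl / 2.0
    x_pivot = x0 + hl * 0.92
    if spec.family == "other":
        strokes.append(("bar", (x0, -hw / 2, x0 + hl, hw / 2, spec.jaw_curve)))
        tip_box = (x0 + hl - 0.06, -0.08, x0 + hl + 0.02, 0.08)
        return strokes, tip_box
    # handle shaft(s)
    if spec.rings:
        strokes.append(("ring", (x0 - 0.035, -0.055, hw)))
        strokes.append(("ring", (x0 - 0.035, 0.055, hw)))
        strokes.append(("line", ((x0, -0.045), (x_pivot, 0.0), hw)))
        strokes.append(("line", ((x0, 0.045), (x_pivot, 0.0), hw)))
    else:
        strokes.append(("line", ((x0, -0.02), (x_pivot, 0.0), hw)))
        strokes.append(("line", ((x0, 0.02), (x_pivot, 0.0), hw)))
    # jaws
    half = math.radians(spec.open_angle if state == "open" else 2.0)
    jl = spec.jaw_len
    for sign in (-1.0, 1.0):
        dx, dy = jl * math.cos(half), jl * math.sin(half) * sign
        x_mid, y_mid = x_pivot + dx * 0.55, dy * 0.55
        x_tip = x_pivot + dx + spec.jaw_curve * 0.3
        y_tip = dy + spec.jaw_curve * sign * 0.8
        strokes.append(("line", ((x_pivot, 0.0), (x_mid, y_mid), hw * 0.8)))
        strokes.append(("line", ((x_mid, y_mid), (x_tip, y_tip), hw * 0.6)))
        if spec.tip_roundness > 0:
            strokes.append(("blob", (x_tip, y_tip, spec.tip_roundness)))
        for t in range(spec.serration):
            frac = 0.55 + 0.4 * (t + 1) / (spec.serration + 1)
            sx = x_pivot + dx * frac
            sy = dy * frac
            strokes.append(("line", ((sx, sy), (sx, sy - sign * 0.015), hw * 0.3)))
    x_tip_max = x_pivot + jl + abs(spec.jaw_curve) + spec.tip_roundness + 0.02
    tip_lo = x_pivot + jl * 0.5
    half_h = jl * math.sin(math.radians(spec.open_angle)) + abs(spec.jaw_curve) + spec.tip_roundness + 0.04
    tip_box = (tip_lo, -half_h, x_tip_max, half_h)
    return strokes, tip_box


def _background(size: int, lighting: str, rng: np.random.Generator) -> np.ndarray:
    """Near-black cloth texture (mean intensity well below 10% full scale)."""
    base = 12 if lighting == "day" else 6
    small = rng.normal(base, 3.0, (size // 8, size // 8))
    img = Image.fromarray(np.clip(small, 0, 25).astype(np.uint8), "L")
    tex = np.asarray(img.resize((size, size), Image.BILINEAR), dtype=np.uint8)
    return np.stack([tex, tex, tex], axis=-1)


def render_instrument(spec: ClassSpec, pose: Pose, rng: np.random.Generator,
                      size: int = 512, manifest: DatasetManifest | None = None,
                      return_tip_box: bool = False):
    """Render one tool image (PIL RGB).

    The same ``spec``, ``pose`` and generator state produce byte-identical
    images.  ``return_tip_box`` additionally returns the pixel bounding box
    of the fore-end region in which fine-grained partners may differ.
    """
    pose.validate(manifest)
    arr = _background(size, pose.lighting, rng)
    img = Image.fromarray(arr, "RGB")
    draw = ImageDraw.Draw(img)
    foreshorten = math.sin(math.radians(pose.angle))
    if pose.lighting == "day":
        body, edge = 168, 210
    else:
        body, edge = 110, 235
    strokes, tip_box = _tool_strokes(spec, pose.state)

    def px(points):
        return _transform(points, pose.rotation, foreshorten, size)

    for kind, payload in strokes:
        if kind == "line":
            (p1, p2, w) = payload
            (x1, y1), (x2, y2) = px([p1, p2])
            draw.line([(x1, y1), (x2, y2)], fill=(body, body, body),
                      width=max(int(w * size), 1))
            # specular streak along the stroke
            draw.line([(x1, y1), (x2, y2)], fill=(edge, edge, edge),
                      width=max(int(w * size * 0.3), 1))
        elif kind == "bar":
            x1, y1, x2, y2, curve = payload
            poly = [(x1, y1), (x2, y1 + curve), (x2, y2 + curve), (x1, y2)]
            draw.polygon(px(poly), fill=(body, body, body),
                         outline=(edge, edge, edge))
        elif kind == "ring":
            cx, cy, w = payload
            r = 0.045
            pts = [(cx + r * math.cos(a), cy + r * math.sin(a))
                   for a in np.linspace(0, 2 * math.pi, 24, endpoint=False)]
            draw.line(px(pts) + px(pts[:1]), fill=(body, body, body),
                      width=max(int(w * size), 1))
        elif kind == "blob":
            cx, cy, r = payload
            pts = [(cx + r * math.cos(a), cy + r * math.sin(a))
                   for a in np.linspace(0, 2 * math.pi, 24, endpoint=False)]
            draw.polygon(px(pts), fill=(body, body, body),
                         outline=(edge, edge, edge))
    if return_tip_box:
        x1, y1, x2, y2 = tip_box
        corners = px([(x1, y1), (x2, y1), (x2, y2), (x1, y2)])
        xs = [p[0] for p in corners]
        ys = [p[1] for p in corners]
        box = (max(min(xs), 0), max(min(ys), 0),
               min(max(xs), size), min(max(ys), size))
        return img, box
    return img


# ---------------------------------------------------------------------------
# dataset generation, indexing, splitting
# ---------------------------------------------------------------------------

@dataclass
class IndexRecord:
    path: str
    label: int
    class_name: str
    state: str
    angle: float
    rotation: float
    lighting: str
    split: str = ""


@dataclass
class DatasetIndex:
    records: list = field(default_factory=list)
    classes: tuple = ()

    def by_split(self, split: str) -> "DatasetIndex":
        return DatasetIndex([r for r in self.records if r.split == split],
                            self.classes)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "label", "class", "state", "angle",
                        "rotation", "lighting", "split"])
            for r in self.records:
                w.writerow([r.path, r.label, r.class_name, r.state,
                            f"{r.angle:.4f}", f"{r.rotation:.4f}",
                            r.lighting, r.split])

    @classmethod
    def from_csv(cls, path, classes=()) -> "DatasetIndex":
        recs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                recs.append(IndexRecord(
                    path=row["path"], label=int(row["label"]),
                    class_name=row["class"], state=row["state"],
                    angle=float(row["angle"]), rotation=float(row["rotation"]),
                    lighting=row["lighting"], split=row.get("split", "")))
        if not classes:
            classes = tuple(sorted({r.class_name for r in recs}))
        return cls(recs, classes)


def sample_pose(spec: ClassSpec, manifest: DatasetManifest,
                rng: np.random.Generator) -> Pose:
    lo, hi = manifest.side_view_angle_range
    return Pose(
        state=STATES[rng.integers(2)] if spec.has_state else "closed",
        angle=float(rng.uniform(lo, hi)),
        rotation=float(rng.uniform(0.0, 360.0)),
        lighting=manifest.lighting_modes[rng.integers(len(manifest.lighting_modes))],
    )


def generate_dataset(manifest: DatasetManifest, out_dir,
                     overwrite: bool = False) -> DatasetIndex:
    """Write the class-per-directory image tree, manifest copy and CSV index."""
    out_dir = Path(out_dir)
    index_path = out_dir / "index.csv"
    if index_path.exists() and not overwrite:
        raise FileExistsError(f"{index_path} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = default_class_specs()
    records = []
    for label, cname in enumerate(manifest.classes):
        spec = specs.get(cname, ClassSpec(name=cname, family="other"))
        cdir = out_dir / cname.replace(" ", "_")
        cdir.mkdir(exist_ok=True)
        rng = np.random.default_rng([manifest.seed, label])
        for i in range(manifest.per_class):
            pose = sample_pose(spec, manifest, rng)
            img = render_instrument(spec, pose, rng, manifest.image_size, manifest)
            rel = f"{cdir.name}/{i:04d}.png"
            img.save(out_dir / rel)
            records.append(IndexRecord(
                path=rel, label=label, class_name=cname, state=pose.state,
                angle=pose.angle, rotation=pose.rotation,
                lighting=pose.lighting))
    (out_dir / "manifest.json").write_text(manifest.to_json())
    index = DatasetIndex(records, manifest.classes)
    index.to_csv(index_path)
    return index


def render_arrays(manifest: DatasetManifest, size: int | None = None):
    """In-memory variant of :func:`generate_dataset`: returns (X, y, index)
    with X of shape (n, 3, size, size) in [0, 1].  Used for desk-scale
    training without touching the filesystem."""
    size = size or manifest.image_size
    specs = default_class_specs()
    imgs, labels, records = [], [], []
    for label, cname in enumerate(manifest.classes):
        spec = specs.get(cname, ClassSpec(name=cname, family="other"))
        rng = np.random.default_rng([manifest.seed, label])
        for i in range(manifest.per_class):
            pose = sample_pose(spec, manifest, rng)
            img = render_instrument(spec, pose, rng, size, manifest)
            imgs.append(np.asarray(img, dtype=np.float64).transpose(2, 0, 1) / 255.0)
            labels.append(label)
            records.append(IndexRecord(
                path=f"<memory>/{cname}/{i}", label=label, class_name=cname,
                state=pose.state, angle=pose.angle, rotation=pose.rotation,
                lighting=pose.lighting))
    return np.stack(imgs), np.asarray(labels), DatasetIndex(records, manifest.classes)


def split_train_test(index: DatasetIndex, ratio: float = 0.6,
                     seed: int = 0) -> DatasetIndex:
    """Stratified train/test split; train fraction ``ratio`` (3:2 default),
    per-class counts rounded toward train."""
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = DatasetIndex([IndexRecord(**vars(r)) for r in index.records],
                       index.classes)
    by_class = {}
    for i, r in enumerate(out.records):
        by_class.setdefault(r.label, []).append(i)
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        if len(idxs) < 2:
            raise ValueError(f"class {label} has fewer than 2 samples")
        n_train = int(math.ceil(ratio * len(idxs)))
        perm = rng.permutation(len(idxs))
        for j, k in enumerate(perm):
            out.records[idxs[k]].split = "train" if j < n_train else "test"
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

#: fallback channel statistics for external natural-image folder trees
NATURAL_IMAGE_MEAN = (0.485, 0.456, 0.406)
NATURAL_IMAGE_STD = (0.229, 0.224, 0.225)


@dataclass
class PreprocessConfig:
    crop_size: int = 224                  # Table-3 scale knob {112,224,336,448}
    resize_size: int | None = None        # default: crop_size * 256 / 224
    train_flips: bool = True
    eval_flips: bool = False              # "--paper-tta" behavior when True
    crop_scale_range: tuple = (0.3, 1.0)
    mean: tuple = NATURAL_IMAGE_MEAN
    std: tuple = NATURAL_IMAGE_STD

    @property
    def resize(self) -> int:
        return self.resize_size or int(round(self.crop_size * 256 / 224))


def preprocess(image, mode: str, cfg: PreprocessConfig | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Resize / crop / flip / normalize one RGB image to (3, S, S) float64."""
    cfg = cfg or PreprocessConfig()
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    rng = rng or np.random.default_rng(0)
    if isinstance(image, np.ndarray):
        if image.ndim == 3 and image.shape[0] == 3:
            image = image.transpose(1, 2, 0)
        if image.dtype != np.uint8:
            image = np.clip(image * 255.0, 0, 255).astype(np.uint8)
        image = Image.fromarray(image, "RGB")
    if image.mode != "RGB":
        raise ValueError(f"expected RGB image, got mode {image.mode!r}")
    s = cfg.resize
    image = image.resize((s, s), Image.BILINEAR)
    c = cfg.crop_size
    if mode == "train":
        # random resized crop: random area fraction & position, then rescale
        frac = float(rng.uniform(*cfg.crop_scale_range)) ** 0.5
        side = max(int(round(frac * s)), 8)
        x0 = int(rng.integers(0, s - side + 1))
        y0 = int(rng.integers(0, s - side + 1))
        image = image.crop((x0, y0, x0 + side, y0 + side)).resize((c, c), Image.BILINEAR)
        flips = cfg.train_flips
    else:
        off = (s - c) // 2
        image = image.crop((off, off, off + c, off + c))
        flips = cfg.eval_flips
    if flips:
        if rng.integers(2):
            image = image.transpose(Image.FLIP_LEFT_RIGHT)
        if rng.integers(2):
            image = image.transpose(Image.FLIP_TOP_BOTTOM)
    arr = np.asarray(image, dtype=np.float64).transpose(2, 0, 1) / 255.0
    mean = np.asarray(cfg.mean).reshape(3, 1, 1)
    std = np.asarray(cfg.std).reshape(3, 1, 1)
    return (arr - mean) / std


def load_arrays(root, index: DatasetIndex, split: str,
                cfg: PreprocessConfig | None = None, mode: str = "eval",
                seed: int = 0):
    """Load and preprocess one split of an on-disk dataset tree."""
    root = Path(root)
    rng = np.random.default_rng(seed)
    recs = [r for r in index.records if r.split == split] if split else index.records
    if not recs:
        raise ValueError(f"no records in split {split!r}")
    xs = np.stack([
        preprocess(Image.open(root / r.path).convert("RGB"), mode, cfg, rng)
        for r in recs
    ])
    ys = np.asarray([r.label for r in recs])
    return xs, ys


def compute_channel_stats(x: np.ndarray) -> tuple:
    """Per-channel mean/std of a (n, 3, H, W) array in [0, 1]."""
    mean = x.mean(axis=(0, 2, 3))
    std = x.std(axis=(0, 2, 3))
    return tuple(mean.tolist()), tuple(np.maximum(std, 1e-6).tolist())
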