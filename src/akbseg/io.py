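"""Reading and writing images and instance annotations.

Supported label formats:

* YOLO-seg text files: one line per instance,
  ``class x1 y1 x2 y2 ...`` with polygon vertices normalized to [0, 1].
* COCO JSON: a single file with images / annotations / categories and
  polygon segmentations in absolute pixel coordinates.

Polygons are rasterized to binary instance masks with skimage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage
from skimage.draw import polygon as draw_polygon

__all__ = ["read_image", "write_image", "polygon_to_mask", "mask_to_polygon",
           "write_yolo_labels", "read_yolo_labels", "write_coco",
           "read_coco", "letterbox", "unletterbox_box"]


def read_image(path) -> np.ndarray:
    """Load PNG/TIFF as uint8; 16-bit input is min-max scaled to 8-bit."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.dtype == np.uint16:
        lo, hi = int(arr.min()), int(arr.max())
        span = max(hi - lo, 1)
        arr = ((arr.astype(np.float64) - lo) * 255.0 / span).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(np.asarray(arr, dtype=np.float64)), 0, 255).astype(np.uint8)
    return arr


def write_image(path, img: np.ndarray):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if np.issubdtype(img.dtype, np.floating):
        img = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), img)
    else:
        PILImage.fromarray(img).save(path)


def polygon_to_mask(poly_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (n, 2) polygon in absolute (x, y) pixel coords."""
    poly_xy = np.asarray(poly_xy, dtype=np.float64)
    rr, cc = draw_polygon(poly_xy[:, 1], poly_xy[:, 0], shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def mask_to_polygon(mask: np.ndarray, n_points: int = 64) -> np.ndarray:
    """Approximate contour of the largest component as an (n, 2) (x, y) polygon."""
    from skimage import measure
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no contour")
    contour = max(contours, key=len)  # (row, col)
    idx = np.linspace(0, len(contour) - 1, min(n_points, len(contour))).astype(int)
    pts = contour[idx]
    return np.stack([pts[:, 1], pts[:, 0]], axis=1)


# --------------------------------------------------------------- YOLO-seg

def write_yolo_labels(path, polygons_norm: list[np.ndarray], class_ids=None):
    """Write normalized (x, y in [0,1]) polygons, one instance per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    class_ids = class_ids or [0] * len(polygons_norm)
    lines = []
    for cid, poly in zip(class_ids, polygons_norm):
        poly = np.clip(np.asarray(poly, dtype=np.float64), 0.0, 1.0)
        coords = " ".join(f"{v:.6f}" for v in poly.ravel())
        lines.append(f"{cid} {coords}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path) -> tuple[list[int], list[np.ndarray]]:
    class_ids, polys = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 7 or len(parts) % 2 == 0:
            raise ValueError(f"{path}:{ln}: malformed polygon line")
        class_ids.append(int(parts[0]))
        vals = np.asarray([float(v) for v in parts[1:]])
        polys.append(vals.reshape(-1, 2))
    return class_ids, polys


# ------------------------------------------------------------------ COCO

def write_coco(path, records: list[dict]):
    """Write a COCO-style JSON. `records`: dicts with keys file_name,
    height, width, polygons (list of (n,2) absolute (x,y) arrays)."""
    images, annotations = [], []
    ann_id = 1
    for img_id, rec in enumerate(records, start=1):
        images.append({"id": img_id, "file_name": rec["file_name"],
                       "height": int(rec["height"]), "width": int(rec["width"])})
        for poly in rec["polygons"]:
            poly = np.asarray(poly, dtype=np.float64)
            xs, ys = poly[:, 0], poly[:, 1]
            mask = polygon_to_mask(poly, (rec["height"], rec["width"]))
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": 1,
                "segmentation": [poly.ravel().round(2).tolist()],
                "bbox": [float(xs.min()), float(ys.min()),
                         float(xs.max() - xs.min()), float(ys.max() - ys.min())],
                "area": float(mask.sum()), "iscrowd": 0})
            ann_id += 1
    doc = {"images": images, "annotations": annotations,
           "categories": [{"id": 1, "name": "cell"}]}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))


def read_coco(path) -> list[dict]:
    doc = json.loads(Path(path).read_text())
    by_img = {im["id"]: {"file_name": im["file_name"], "height": im["height"],
                         "width": im["width"], "polygons": []}
              for im in doc["images"]}
    for ann in doc["annotations"]:
        seg = np.asarray(ann["segmentation"][0], dtype=np.float64).reshape(-1, 2)
        by_img[ann["image_id"]]["polygons"].append(seg)
    return [by_img[k] for k in sorted(by_img)]


# ------------------------------------------------------------- letterbox

def letterbox(img: np.ndarray, size: int, pad_value: int = 114):
    """Resize keeping aspect ratio and pad to `size` x `size`.

    Returns (padded float32 image on the input's intensity scale, scale,
    (pad_x, pad_y)). `pad_value` is on the 8-bit scale and is rescaled for
    unit-range float input."""
    if np.issubdtype(np.asarray(img).dtype, np.floating):
        pad_value = pad_value / 255.0
    h, w = img.shape[:2]
    scale = size / max(h, w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    if (nh, nw) == (h, w):
        resized = img.astype(np.float32)
    else:
        from skimage.transform import resize as sk_resize
        resized = sk_resize(img.astype(np.float32), (nh, nw) + img.shape[2:],
                            order=1, anti_aliasing=scale < 1.0,
                            preserve_range=True)
    pad_y, pad_x = (size - nh) // 2, (size - nw) // 2
    shape = (size, size) + img.shape[2:]
    out = np.full(shape, float(pad_value), np.float32)
    out[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    return out, scale, (pad_x, pad_y)


def unletterbox_box(box, scale: float, pad: tuple[int, int],
                    orig_shape: tuple[int, int]) -> np.ndarray:
    """Map an (x1,y1,x2,y2) box from the letterboxed frame back to the
    original image frame, clipped to its bounds."""
    x1, y1, x2, y2 = box
    px, py = pad
    h, w = orig_shape
    out = np.array([(x1 - px) / scale, (y1 - py) / scale,
                    (x2 - px) / scale, (y2 - py) / scale])
    out[[0, 2]] = np.clip(out[[0, 2]], 0, w)
    out[[1, 3]] = np.clip(out[[1, 3]], 0, h)
    return out
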