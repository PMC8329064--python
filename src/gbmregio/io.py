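"""File formats: indexed-PNG masks, RGB slides, TSV tables, GMT gene sets."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .segmentation import CLASS_MAP, LabeledSlide


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a label mask as single-channel indexed PNG with the display palette."""
    im = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    im.putpalette(CLASS_MAP.palette())
    im.save(path)


def read_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("P") if im.mode != "P" else im,
                          dtype=np.uint8)


def write_slide_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_slide_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_slide_pair(slide: LabeledSlide, stem: Path) -> tuple[Path, Path]:
    img_path = stem.with_suffix(".png")
    msk_path = stem.parent / (stem.name + "_mask.png")
    write_slide_png(slide.image, img_path)
    write_mask_png(slide.mask, msk_path)
    return img_path, msk_path


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_mask_manifest(path) -> dict[str, list[str]]:
    """Manifest TSV (patient_id, mask_path) -> patient -> list of paths."""
    df = pd.read_csv(path, sep="\t")
    if not {"patient_id", "mask_path"} <= set(df.columns):
        raise ValueError("manifest needs patient_id and mask_path columns")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["patient_id"]), []).append(str(row["mask_path"]))
    return out


def write_gmt(gene_sets: dict[str, set | list], path,
              descriptions: dict[str, str] | None = None) -> None:
    """GMT: one tab-separated line per set (name, description, genes...).

    List-valued sets keep their order (rank matters for references);
    set-valued ones are written sorted.
    """
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            ordered = list(genes) if isinstance(genes, (list, tuple)) else sorted(genes)
            fh.write("\t".join([name, desc, *ordered]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT -> name -> (description, ordered gene list)."""
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = (parts[1], parts[2:])
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
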