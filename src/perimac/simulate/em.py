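"""Ground-truthed synthetic EM-scale scenes.

A scene is a horizontal endothelial ribbon on a lighter background (the
lumen above, tissue below); its luminal lining is the ordered pixel
chain along the ribbon's upper boundary. Dark circular vesicles of
specified diameter are planted fully inside the ribbon, decoys outside
it, and fenestrae are carved as gaps of known length through the
lining. Truth rows record every vesicle's centre, diameter and
endothelium membership, and the scene's constructed fenestrae lining
fraction. No attempt is made to mimic real EM texture — only the
geometry and contrast the quantification consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..em import EMScene, classify_size
from .config import EMSimConfig

__all__ = ["generate_em_scene"]


def _place_discs(rng, n, diam_px, y_range, x_range, existing, min_sep_px, max_attempts=300):
    """Rejection-sample n disc centres with pairwise clearance."""
    placed = []
    for d in diam_px:
        r = d / 2.0
        ok = False
        for _ in range(max_attempts):
            y = rng.uniform(y_range[0] + r, y_range[1] - r)
            x = rng.uniform(x_range[0] + r, x_range[1] - r)
            if all(
                np.hypot(y - py, x - px) >= (r + pr + min_sep_px)
                for py, px, pr in existing + placed
            ):
                placed.append((y, x, r))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place a {d:.0f} px vesicle without overlap; "
                "scene too crowded"
            )
    return placed


def generate_em_scene(config: EMSimConfig) -> tuple[EMScene, pd.DataFrame, float]:
    """Generate one scene; returns (scene, vesicle truth, true fenestrae
    lining fraction in percent)."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    r0, r1 = config.ribbon_rows
    npp = config.nm_per_pixel

    img = np.full((h, w), config.background_level, dtype=float)
    img[r0:r1, :] = config.ribbon_level
    endo = np.zeros((h, w), dtype=bool)
    endo[r0:r1, :] = True

    # luminal lining: the ribbon's top boundary row, ordered along x
    lining = np.stack(
        [np.full(w, r0, dtype=int), np.arange(w, dtype=int)], axis=1
    )

    # fenestrae: notches carved through the lining, lengths known exactly
    gap_px_total = 0
    notch_cols = np.zeros(w, dtype=bool)
    for start_frac, length_nm in config.fenestrae:
        k = max(int(round(length_nm / npp)), 1)
        c0 = int(round(start_frac * w))
        c1 = min(c0 + k, w)
        depth = min(config.fenestra_depth_px, r1 - r0)
        img[r0 : r0 + depth, c0:c1] = config.background_level
        endo[r0 : r0 + depth, c0:c1] = False
        notch_cols[c0:c1] = True
        gap_px_total += c1 - c0
    true_fraction = 100.0 * gap_px_total / w

    # vesicles inside the ribbon (clear of the notch depth), decoys below
    inside_d_px = [d / npp for d in config.vesicle_diameters_nm]
    margin = config.fenestra_depth_px + 2
    placed_in = _place_discs(
        rng, len(inside_d_px), inside_d_px,
        (r0 + margin, r1 - 2), (2, w - 2), [], config.min_separation_px,
    )
    decoy_d_px = [d / npp for d in config.decoy_diameters_nm]
    placed_out = _place_discs(
        rng, len(decoy_d_px), decoy_d_px,
        (r1 + 4, h - 2), (2, w - 2), placed_in, config.min_separation_px,
    )

    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for (y, x, r), d_nm, inside in [
        *[
            (p, d, True)
            for p, d in zip(placed_in, config.vesicle_diameters_nm)
        ],
        *[
            (p, d, False)
            for p, d in zip(placed_out, config.decoy_diameters_nm)
        ],
    ]:
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        img[disc] = config.vesicle_level
        rows.append(
            {
                "row": y,
                "col": x,
                "diameter_nm": d_nm,
                "size_class": classify_size(d_nm),
                "inside_endothelium": inside,
            }
        )

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(img, 0.0, 255.0)

    scene = EMScene(
        image=img,
        nm_per_pixel=npp,
        endothelium_mask=endo,
        lining_paths=[lining],
    )
    truth = pd.DataFrame(
        rows,
        columns=["row", "col", "diameter_nm", "size_class", "inside_endothelium"],
    )
    return scene, truth, true_fraction
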