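"""HDF5 serialization of phantom datasets, stage matrices and CT images.

Layout: ``/phantoms/<id>/{density,sound_speed}``, per-inclusion masks under
``/phantoms/<id>/masks/<k>`` with inclusion metadata as attributes, stage
matrices under ``/phantoms/<id>/stages/<stage>`` and the CT image under
``/phantoms/<id>/ct``.
"""

from __future__ import annotations

import numpy as np

from us2ct.ct_sim import CTImage
from us2ct.phantoms import Inclusion, Phantom, PhantomConfig


def save_phantom(h5group, phantom: Phantom) -> None:
    g = h5group
    g.create_dataset("density", data=phantom.density_map, compression="gzip", track_times=False)
    g.create_dataset("sound_speed", data=phantom.sound_speed_map, compression="gzip", track_times=False)
    g.attrs["flavour"] = phantom.flavour
    cfg = phantom.config
    for key in ("axial_extent", "transverse_extent", "elevation_extent",
                "grid_spacing", "inclusion_radius_min", "inclusion_radius_max",
                "max_inclusions"):
        g.attrs[key] = getattr(cfg, key)
    if cfg.seed is not None:
        g.attrs["seed"] = cfg.seed
    mg = g.create_group("masks")
    for k, (inc, mask) in enumerate(zip(phantom.inclusions, phantom.masks)):
        d = mg.create_dataset(str(k), data=mask.astype(np.uint8), compression="gzip", track_times=False)
        d.attrs["centre"] = inc.centre
        d.attrs["radius"] = inc.radius
        d.attrs["material"] = inc.material
        d.attrs["echo_class"] = inc.echo_class
        d.attrs["ct_visible"] = inc.ct_visible


def load_phantom(h5group) -> Phantom:
    g = h5group
    cfg = PhantomConfig(
        axial_extent=float(g.attrs["axial_extent"]),
        transverse_extent=float(g.attrs["transverse_extent"]),
        elevation_extent=float(g.attrs["elevation_extent"]),
        grid_spacing=float(g.attrs["grid_spacing"]),
        inclusion_radius_min=float(g.attrs["inclusion_radius_min"]),
        inclusion_radius_max=float(g.attrs["inclusion_radius_max"]),
        max_inclusions=int(g.attrs["max_inclusions"]),
        flavour=str(g.attrs["flavour"]),
        seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
    )
    inclusions, masks = [], []
    mg = g["masks"]
    for k in sorted(mg.keys(), key=int):
        d = mg[k]
        inclusions.append(
            Inclusion(
                centre=tuple(float(v) for v in d.attrs["centre"]),
                radius=float(d.attrs["radius"]),
                material=str(d.attrs["material"]),
                echo_class=str(d.attrs["echo_class"]),
                ct_visible=bool(d.attrs["ct_visible"]),
            )
        )
        masks.append(d[...].astype(bool))
    return Phantom(
        density_map=g["density"][...],
        sound_speed_map=g["sound_speed"][...],
        inclusions=inclusions,
        masks=masks,
        flavour=str(g.attrs["flavour"]),
        config=cfg,
    )


def save_stage(h5group, stage_name: str, data: np.ndarray, dt: float, c_bar: float) -> None:
    sg = h5group.require_group("stages")
    d = sg.create_dataset(stage_name, data=data.astype(np.float32), compression="gzip", track_times=False)
    d.attrs["dt"] = dt
    d.attrs["c_bar"] = c_bar


def save_ct(h5group, ct: CTImage) -> None:
    d = h5group.create_dataset("ct", data=ct.data.astype(np.float32), compression="gzip", track_times=False)
    d.attrs["n_sirt_iterations"] = ct.n_sirt_iterations
    d.attrs["spacing"] = ct.spacing
    if ct.phantom_region is not None:
        r, c = ct.phantom_region
        d.attrs["region"] = (r.start, r.stop, c.start, c.stop)


def load_ct(h5group) -> CTImage:
    d = h5group["ct"]
    region = None
    if "region" in d.attrs:
        r0, r1, c0, c1 = (int(v) for v in d.attrs["region"])
        region = (slice(r0, r1), slice(c0, c1))
    return CTImage(
        data=d[...].astype(np.float64),
        n_sirt_iterations=int(d.attrs["n_sirt_iterations"]),
        phantom_region=region,
        spacing=float(d.attrs["spacing"]),
    )


def save_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (255 = inside)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def load_mask_png(path) -> np.ndarray:
    """Read a binary mask PNG (any non-zero pixel counts as inside); used
    to import reader-drawn segmentations."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return img > 0


def save_image_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] grayscale or RGB raster as an 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.asarray(image) * 255, 0, 255).astype(np.uint8))
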