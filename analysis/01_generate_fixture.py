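"""Generate the synthetic study set: 4 marbling classes x 6 slices.

The four classes mimic a quality-designation gradient through their fat
fraction (10/15/20/30 %); every slice carries ±30 % multiplicative
shading at 128-px scale plus mild sensor noise, the conditions under
which the filtered and unfiltered segmentation paths diverge.  Images,
ground-truth masks and a JSON manifest go to results/fixture/.
"""

import sys
from dataclasses import asdict
from pathlib import Path

from hamfrac import SliceParams, fat_fraction, make_class_fixture
from hamfrac import io as hio

SEED = 20
N_PER_CLASS = 6
CLASSES = {
    f"f{int(t * 100):02d}": SliceParams(
        fat_fraction_target=t,
        illumination_amplitude=0.3,
        illumination_scale_px=128.0,
        noise_sd=3.0,
    )
    for t in (0.10, 0.15, 0.20, 0.30)
}


def main() -> None:
    out = Path("results/fixture")
    out.mkdir(parents=True, exist_ok=True)
    samples = make_class_fixture(CLASSES, N_PER_CLASS, SEED)
    manifest, counters = [], {}
    for s in samples:
        k = counters.get(s.class_label, 0)
        counters[s.class_label] = k + 1
        stem = f"{s.class_label}_{k:03d}"
        hio.save_image(s.image, out / f"{stem}.png")
        hio.save_mask_png(s.mask, out / f"{stem}_mask.png")
        manifest.append(
            {
                "image": f"{stem}.png",
                "mask": f"{stem}_mask.png",
                "class_label": s.class_label,
                "fat_fraction": fat_fraction(s.mask),
                "params": asdict(s.params),
            }
        )
    hio.write_json({"seed": SEED, "images": manifest}, out / "fixture.json")
    print(f"wrote {len(samples)} slices ({len(CLASSES)} classes x {N_PER_CLASS}) to {out}")
    for label in CLASSES:
        fracs = [m["fat_fraction"] for m in manifest if m["class_label"] == label]
        print(f"  {label}: realized fat fraction "
              f"{min(fracs):.3f}-{max(fracs):.3f}")


if __name__ == "__main__":
    sys.exit(main())
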