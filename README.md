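# thermomap

Cross-modal RGB→infrared region mapping and head-region thermometry for
dual-channel animal thermography.

## The problem

Heat stress in broiler chickens shows up as elevated surface temperature of
the featherless head appendages — comb, eye, beak and wattle. Dual-channel
cameras capture a high-resolution RGB image (2688×1520) alongside a
low-resolution IR temperature matrix (384×288), and segmentation models
that delineate those regions run on the RGB channel. thermomap moves the
segmentation masks onto the IR grid through the rig's calibrated geometry
so temperatures can be read from exactly the right pixels, instead of from
hand-drawn boxes that mix in background.

For a pixel (u, v) in the RGB frame the per-point chain is

    normalize      x = (u − cx)/fx,  y = (v − cy)/fy
    undistort      invert the Brown–Conrady model (k1, k2, p1, p2, k3)
    back-project   P = (x·d, y·d, d)        — working depth d in mm
    rig transform  P' = R·P + t             — RGB frame → IR frame
    project        IR pixel via K_ir with forward distortion

Whole masks travel as contours: outer boundaries of each region's connected
components are traced, mapped pointwise, and filled on the IR grid
(nonzero winding, edge-inclusive). The toolkit also calibrates the rig from
checkerboard corners (Zhang's method with joint two-channel refinement),
quantifies sensitivity to depth error across [580, 620] mm (with the
closed-form check offset = fx·b·|1/600 − 1/d| for pure-baseline rigs),
evaluates segmentations (per-class IoU, MIoU, MPA), and provides focal /
dice / BCE mask losses plus a pluggable segmenter contract. A seeded
synthetic-scene generator emulates rigs, checkerboard observations,
head-region masks and temperature fields, since no real dataset is
publicly available.

## Worked example

```python
import thermomap as tm

rig = tm.make_rig("realistic", seed=7)          # synthetic dual-channel rig
scene = tm.make_scene(tm.SceneSpec(seed=5), rig=rig)

roi = tm.map_label_mask(scene.rgb_mask, rig, depth=600.0)
for stat in tm.region_stats(scene.temps, roi):
    print(f"{stat.region.name.lower():7s} {stat.mean:6.2f} degC "
          f"({stat.pixel_count} px)")
```

prints

```
comb     38.52 degC (446 px)
eye      36.52 degC (249 px)
beak     33.46 degC (125 px)
wattle   37.99 degC (350 px)
```

— the generating means of this scene are comb 38.5, eye 36.5, beak 33.5
and wattle 38.0 °C, so the mapped masks are reading the right pixels: each
recovered mean is within a few hundredths of a degree, i.e. within the
sampling noise of the σ = 0.3 °C pixel noise over a few hundred pixels.

The same steps are available from the shell:

```sh
thermomap simulate --preset realistic --seed 7 --out-dir scene7/
thermomap map --rig scene7/rig.json --mask scene7/rgb_mask.png --depth 600 --out-dir roi/
thermomap measure --rig scene7/rig.json --roi-dir roi/ --temps scene7/temps.csv --out temps.json
thermomap sweep-depth --rig scene7/rig.json --masks 'scene7/rgb_mask.png' --out sweep.csv
thermomap eval-seg --truth gt.png --pred pred.png --classes 5 --out report.json
```

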