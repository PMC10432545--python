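"""Generate the synthetic five-class study scene.

Builds the seeded demo mosaic (water, tree canopy, grassland, bare land,
impervious surface; 300x300 cells of 30 m) whose class-mean LSTs are the
Luoping built-up-area values, forward-models thermal radiance through the
single-channel physics, and writes the grids plus the scene recipe under
results/scene/.
"""

from pathlib import Path

from canopytherm.synthetic_scene import demo_scene_spec, generate_scene, write_scene

OUT = Path(__file__).resolve().parents[1] / "results" / "scene"
SEED = 42


def main():
    scene = generate_scene(demo_scene_spec(seed=SEED))
    write_scene(scene, OUT)
    n = scene.landcover.grid.size
    print(f"scene: {scene.landcover.shape[0]}x{scene.landcover.shape[1]} "
          f"cells ({n}), cell size {scene.landcover.cell_size} m, seed {SEED}")
    for name in ("lst_true", "red", "nir", "radiance"):
        print(f"  wrote {OUT / (name + '.txt')}")
    print(f"  wrote {OUT / 'landcover.txt'} and scene_spec.json")


if __name__ == "__main__":
    main()
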