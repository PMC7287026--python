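"""Write a labeled synthetic eye dataset to disk.

Generates two images per phenotype class (PNG) plus a manifest CSV with
the class label, disorder level and ground-truth eye geometry of every
image — the same manifest format the CLI and pipeline consume.
"""

from pathlib import Path

from ommaquant import EyeSpec, generate_dataset

out_dir = Path("scratch/example_dataset")
manifest = generate_dataset(2, EyeSpec(), seed=3, out_dir=out_dir)

print(f"wrote {len(manifest)} images to {out_dir}/")
print(manifest[["class", "disorder_level", "center_row", "center_col",
                "n_ommatidia"]].to_string(index=False))
print()
print("disorder_level 0 renders a regular hexagonal wild-type lattice;")
print("level 1 adds full positional jitter, facet fusion, depigmentation")
print("and bristle loss (the gmr>SCA1 phenotype).")
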