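# lobule3d

3D reconstruction and single-cell morphometry of liver lobule tissue from
multi-channel fluorescence stacks.

Quantitative models of liver micro-architecture need all the main tissue
components at once: the bile-canalicular (BC) and sinusoidal networks, the
hepatocytes with their nuclei, the hepatic stellate cells (HSC), the
Kupffer cells (KC), and the central/portal veins (CV/PV) that define the
lobule axis. Deep-tissue fluorescence imaging rarely provides more than
four clean channels, so `lobule3d` couples *virtual staining* — a 3D
convolutional encoder–decoder that predicts the two tubular-network
channels from the phalloidin (actin) channel — with a classical 3D
reconstruction chain, freeing real channels for the sparse cell markers.
The output is a single-cell atlas: per-object volumes, principal-axis
elongation (1 − A3/A1), DNA content and ploidy classes (2n/4n/8n/16n) from
integrated DAPI intensity, nuclearity (e.g. `2×2n`), network radii and
connectivity from centerline graphs, structure volume fractions (excluding
the large veins), hepatocyte contact-surface percentages, KC–HSC contact
sites, inter-nuclear distances, and zonal profiles along ten equal bins of
the CV→PV coordinate `d_CV/(d_CV+d_PV)`.

It is written for computational tissue-biology groups who want the whole
measurement chain testable: a synthetic lobule generator produces
six-marker image stacks with complete ground truth (masks, instance
labels, centerline graphs, per-nucleus DNA content), so every stage has a
parameter-recovery test against known truth.

Core methods, in pipeline order:

* **Virtual staining** — 3-level 3D U-Net-topology regressor (3×3×3
  convolutions, skip connections, linear head) trained on non-overlapping
  64³ phalloidin→marker patch pairs with SGD (momentum 0.9, lr 0.05,
  batch 8, MSE), implemented in numpy with explicit backprop; tiled
  inference with overlap blending.
* **Segmentation** — blockwise maximum-entropy (Kapur) thresholding with a
  trilinearly interpolated threshold field and intermeans refinement;
  morphological cleanup; distance-transform watershed nucleus splitting
  (h-maxima seeds); marching-cubes meshes with Taubin smoothing;
  hepatocyte expansion from nucleus seeds by marker-controlled watershed
  with weak-wall merging for binucleate cells.
* **Network analysis** — topology-preserving thinning to centerline
  graphs, spur pruning, per-node radii from the Euclidean distance
  transform, connectivity statistics.
* **Morphometry & zonation** — the atlas quantities above, with
  mean ± s.e.m. summary tables and CSV/GraphML/TIFF exports.

## Worked example

```python
from lobule3d import LobuleParams, generate_lobule, reconstruct, quantify

image, truth = generate_lobule(LobuleParams(seed=1))   # 128^3, 0.3 um voxels
recon = reconstruct(image)                             # all masks + instances
result = quantify(image, recon)                        # the atlas

print(result["n_hepatocytes"], truth.params.hepatocyte_count)
print(round(result["binucleation_fraction"], 3))
print(round(result["volume_fractions"]["sinusoids"], 3))
print(result["n_hsc"], result["n_kc"])
```

prints

```
91 90
0.363
0.081
16 16
```

— the pipeline recovered 91 cells against the 90 generated hepatocytes, a
binucleate fraction of 0.363 against a realized ground truth of 0.378, a
sinusoid volume fraction of 0.081 against 0.082 generated, and all 16 HSCs
and 16 KCs, from the rendered noisy image alone. `result["atlas"]` holds the
per-cell and per-nucleus tables with mean ± s.e.m. summaries;
`result["profiles"]` the zonal volume-fraction profiles of the HSC/KC
populations.

The same run from a shell:

```sh
lobule3d run --stages simulate,segment,skeletonize,quantify,report --out runs/demo
```

writes the image and ground truth, label maps, centerline GraphML files,
atlas CSVs, plots and a checksummed `manifest.json` under `runs/demo/`.

Training a virtual stainer (desk scale — 8 filters, 32³ patches):

```python
from lobule3d import (UNet3DConfig, extract_patches, train_virtual_stainer,
                      predict_virtual_channel, evaluate_prediction,
                      normalize_channel)

x = normalize_channel(image["phalloidin"])
y = normalize_channel(image["cd13"])
patches = extract_patches(x, y, patch_size=32, val_fraction=0.1, seed=0)
model, report = train_virtual_stainer(
    patches, UNet3DConfig(filters=8, patch_size=32, epochs=10, seed=0))
v_cd13 = predict_virtual_channel(model, x)
```

On a 192³ lobule with 200 patches this reaches a voxelwise Pearson r of
0.87 against the noise-free BC mask and raises the signal-to-background
ratio from 4.6 (raw phalloidin) to 6.4.

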