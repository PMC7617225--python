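# damagemap

Texture-based profiling of DNA damage and immune-cell proximity in thick 3D
fluorescence histology volumes.

In tumor tissue, the staining texture of γH2AX — a chromatin mark that forms
nuclear foci at DNA double-strand breaks — carries information about the
damage/repair state of each cell that plain foci counting discards.
`damagemap` takes a multi-channel confocal z-stack (DAPI, γH2AX, CD8,
optionally pan-protein) plus a 3D nuclei *instance* segmentation from any
external segmenter (e.g. Cellpose), and

1. **identifies** γH2AX+ and CD8+ cells by thresholding each marker channel
   and superimposing the mask on the nuclei segmentation — a cell is
   positive when the overlap fraction |instance ∩ mask| / |instance| reaches
   a threshold; for the membrane-bound CD8 marker the instance is first
   dilated (without ever merging instances) so the perinuclear ring can
   overlap at all;
2. **represents** each γH2AX+ nucleus as a 64×64 patch, summarized two
   ways: four gray-level co-occurrence matrix (GLCM) features — energy
   `Σp²`, contrast `Σ(i−j)²p`, cluster prominence `Σ(i+j−μᵢ−μⱼ)⁴p`,
   correlation `Σ(i−μᵢ)(j−μⱼ)p/σᵢσⱼ` — and a 16-dimensional latent code
   from a VAE-GAN (encoder / generator / discriminator, with the
   discriminator's feature maps serving as a learned similarity metric for
   reconstruction);
3. **clusters** the representations with KMeans into *pseudo texture
   classes* (surrogate phenotype labels, k = 5 by default) and projects
   them to 2D with PCA;
4. **profiles** spherical neighborhoods around each γH2AX+ cell — class
   co-occurrence heatmaps H[i,j] = mean class-j neighbor count around
   class-i centers — and counts γH2AX+ cells near CD8+ cells at radii
   32/64/128 px (10.28/20.56/41.13 µm at the default 0.32125 µm/px lateral
   pitch), then contrasts control vs treated regions with a region-label
   permutation test.

It is aimed at quantitative imaging groups studying DNA-damage response and
its interplay with immune infiltration, who have 3D volumes and a nuclei
segmentation and want reproducible, scriptable profiling. A synthetic-data
module generates fully ground-truthed 3D regions (ellipsoidal nuclei,
planted foci/diffuse textures, CD8 membrane shells) so the entire chain is
testable without microscope data. The VAE-GAN runs on plain numpy — no GPU
or deep-learning framework required.

## Worked example

```python
from damagemap.synthetic_data import SynthSpec, generate_region
from damagemap.segmentation import threshold_channel, build_cell_table, extract_patches
from damagemap.glcm import glcm_table
from damagemap.profiling import (cluster_representations, neighborhood_counts,
                                 cooccurrence_heatmap, cd8_proximity_report,
                                 summarize_proximity)
from damagemap.volume_io import ChannelName

spec = SynthSpec(shape=(32, 128, 128), n_nuclei=60, frac_gh2ax_pos=0.4,
                 n_cd8=6, rng_seed=7, radius_range=(4.0, 7.0))
channels, labels, truth = generate_region(spec)

gh2ax = threshold_channel(channels[ChannelName.GH2AX])        # Otsu
cd8 = threshold_channel(channels[ChannelName.CD8])
cells = build_cell_table(labels, gh2ax, cd8)
print(f"{len(cells.df)} nuclei, {cells.df.gh2ax_pos.sum()} gamma-H2AX+, "
      f"{cells.df.cd8_pos.sum()} CD8+ (threshold {gh2ax.threshold_value:.1f})")

patches = extract_patches(channels[ChannelName.GH2AX], cells, labels)
features = glcm_table(patches)
classes = cluster_representations(features, k=2, seed=0)
print(features.merge(classes.df, on="cell_id").groupby("class_label")
      [["energy", "contrast"]].mean().round(3))

profiles = neighborhood_counts(cells, classes, radius_px=32.0)
H, absent = cooccurrence_heatmap(profiles, k=2)
print("co-occurrence heatmap (radius 32 px):"); print(H.round(2))
print(summarize_proximity(cd8_proximity_report(cells)))
```

prints

```
60 nuclei, 24 gamma-H2AX+, 6 CD8+ (threshold 19.0)
             energy  contrast
class_label
0             0.956     3.295
1             0.937     6.019
co-occurrence heatmap (radius 32 px):
[[3.   1.  ]
 [3.   2.33]]
   radius_px  radius_um  n_cd8  total       mean
0       32.0      10.28      6     17   2.833333
1       64.0      20.56      6     84  14.000000
2      128.0      41.12      6    144  24.000000
```

All 24 planted γH2AX+ nuclei are recovered; the two pseudo texture classes
differ in GLCM contrast (punctate foci vs diffuse fill); the heatmap row i
gives the mean number of class-j neighbors within 32 px of a class-i cell;
and each CD8+ cell sees on average 2.8 damaged cells within 10.28 µm,
rising monotonically with radius.

The same chain runs from the shell via a YAML config:

```bash
damagemap synth --outdir out --shape 32,128,128 --n-nuclei 60 --n-cd8 6 --seed 7
damagemap run --config pipeline.yaml            # synth → segment → glcm →
                                                # train-vaegan → encode →
                                                # cluster → profile → compare
```

Every stage writes CSV outputs with JSON provenance sidecars (config hash,
input hashes, seed) and is skipped on re-run when nothing changed.

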