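# orchard-vqa

Multimodal visual question answering for fruit-tree disease decision-making:
a Tucker-decomposed bilinear fusion head with an element-wise-squared image
projection, a stacked modular co-attention encoder, and a complete
data-preparation / training / evaluation pipeline that runs entirely on
synthetic fixtures (no datasets or pretrained weights required).

The neural layers (attention, fusion, training) run on a small NumPy
reverse-mode autograd included in the package, so everything works on one CPU
with no deep-learning framework installed.

## Layout

| Module | Contents |
| --- | --- |
| `orchard_vqa.corpus` | Triplet records, JSON-lines manifest I/O, split logic (fixed val/test counts, train = remainder), answer vocabulary, synthetic lesion-image corpus generator |
| `orchard_vqa.image_prep` | Intensity normalization, Otsu threshold with floor 5, 40x40 morphological opening, foreground-bbox crop, 448x448 bilinear resize, the five-operator augmentation pipeline, grid + pooled image encoding |
| `orchard_vqa.backbones` | Image-encoder contracts: weight-free `tiny` stand-in and the randomly initialized 152-layer reference residual network (14x14x2048 grid at 448x448) |
| `orchard_vqa.question_prep` | Text normalization, word-piece tokenization padded to 26 tokens, OOV least-squares embedding projection, text augmentation, question-encoder contracts (`tiny` built in; skip-thought / BERT / recurrent are optional plug-ins) |
| `orchard_vqa.coattention` | Multi-head attention, SA and CA units (pre-layer-norm residual blocks), the depth-L modular co-attention stack, attended reduction |
| `orchard_vqa.fusion` | Tucker bilinear fusion, squared-image-projection variant, low-rank core, full-tensor oracle, concat/MLB/MUTAN baselines, additive classifier head |
| `orchard_vqa.model` / `orchard_vqa.engine` | End-to-end model assembly, AdamW training with early stopping, strict-accuracy evaluation per question type, k-fold cross-validation, confusion statistics |
| `orchard_vqa.autograd` / `orchard_vqa.nn` | Minimal autograd tensors, layers, optimizer |

## CLI

```bash
# generate a synthetic corpus (images + JSONL manifest + generation params)
orchard-vqa synth --n-images 40 --val-images 4 --test-images 4 --seed 1 --out corpus/

# re-split an existing manifest
orchard-vqa build --manifest corpus/manifest.jsonl --val-images 4 --test-images 4 --out resplit.jsonl

# five augmented variants of one image plus the draw log
orchard-vqa augment --image corpus/img00000.png --out aug/ --seed 0

# train / evaluate / cross-validate
orchard-vqa train --manifest corpus/manifest.jsonl --config cfg.yaml --seed 0
orchard-vqa eval  --manifest corpus/manifest.jsonl --config cfg.yaml --split val
orchard-vqa cv    --manifest corpus/manifest.jsonl --config cfg.yaml --k 10 --runs 10

# export attention heatmaps for one record
orchard-vqa attend-viz --manifest corpus/manifest.jsonl --record 0 --out viz/
```

The YAML config mirrors the dataclass fields, e.g.:

```yaml
model:    {hidden: 512, heads: 8, L: 4, dropout: 0.5, fusion_variant: tucker_squared,
           t_q: 512, t_v: 512, t_o: 512, R: 15, G: 1, d_z: 2048}
train:    {learning_rate: 0.0001, batch_size: 64, max_epochs: 50}
encoder:  {name: tiny, output_channels: 8, grid_side: 4, question_mode: tiny, question_dim: 16}
```

Full-scale defaults (hidden 512, 8 heads, depth 4, batch 64, lr 1e-4) are the
dataclass defaults; `ModelConfig.tiny(...)` provides the desk-scale settings
used by the tests.

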