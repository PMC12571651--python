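# clinvla

A dual-view radiograph / radiology-report alignment toolkit built around
parameter-efficient adapters:

- **Reversible adapter** — an additive coupling layer with a closed-form
  inverse (`o1 = F(e2) + e1`, `o2 = G(o1) + e2`; `F`/`G` are
  down-projection → ReLU → up-projection maps, He-initialized), so
  embeddings can be mapped into and out of the adapted space losslessly.
- **Transformer-adapt layers** — a language adapter stacked under a task
  adapter (both bottleneck residual adapters) followed by layer
  normalization, inserted into small frozen transformer backbones. In
  downstream mode only the task adapters (and their layer norms) train.
- **Masked dual-view image pipeline** — HU window normalization
  (width 1500 / level −500 → [0, 255]), bilinear resize to 224×224,
  16×16 patchification (196 patches/view), and seeded exact-count 75%
  random masking (49 patches retained per view).
- **Text pipeline** — Findings/Diagnosis section extraction, a
  deterministic pluggable tokenizer, and 128-token pad/truncate with
  sentence-boundary truncation.
- **Alignment losses** — global cosine-distance loss plus a per-region
  local loss, combined as `L = L_global + 0.8 · L_local`; an opt-in
  in-batch contrastive objective is available for toy retrieval training.
- **Retrieval evaluation** — cosine ranking with deterministic
  tie-breaks, P@k, accuracy/F1/AUC (Mann–Whitney with midranks), and
  zero-shot classification by class-prompt similarity.
- **Synthetic data** — dual-view chest phantoms with class-dependent
  lesion geometry and templated reports, so everything runs offline.

Everything is NumPy-based; training runs on a small reverse-mode autodiff
engine (`clinvla.autograd`) — no deep-learning framework required.

## CLI

```sh
clinvla synth --classes 8 --per-class 8 --out data/ --seed 0
clinvla preprocess --in data/ --out pre/ --mask-rate 0.75 --patch 16 \
    --size 224 --window 1500,-500 --seed 0
clinvla train --data data/ --out run/ --objective contrastive \
    --mode pretrain --steps 50 --seed 0
clinvla eval --data data/ --task i2t --k 5,10 --out metrics.json
```

## Layout

| module | contents |
| --- | --- |
| `clinvla.adapters` | reversible + bottleneck adapters, He init, archive I/O |
| `clinvla.image_pipeline` | windowing, resize, patchify, masking, PNG/DICOM I/O |
| `clinvla.text_pipeline` | section extraction, tokenizer, pad/truncate |
| `clinvla.alignment` | multiview aggregation, global/local/contrastive losses |
| `clinvla.models` | frozen transformer backbones + adapter wiring |
| `clinvla.training` | parameter partitioning, AdamW, train loop |
| `clinvla.retrieval` | ranking, P@k, acc/F1/AUC, zero-shot |
| `clinvla.synthetic` | dual-view phantom generator with paired reports |
| `clinvla.autograd` | minimal reverse-mode autodiff over NumPy |
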