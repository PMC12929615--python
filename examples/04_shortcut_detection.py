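"""Exposing shortcut learning with patch saliency.

Builds a poisoned cohort in which the label is driven *only* by a small
bright corner marker (the lesion contrast is zero, so there is nothing
else to learn).  A model trained on it reaches high AUROC — and the patch
saliency map immediately betrays why: the argmax sits in the marker's
patch, not anywhere a lesion could be.  With a post-hoc method one would
have to trust the attribution; here the marker patch's logit *is* the
decision.
"""

import numpy as np

from patchmil import (
    LesionSpec,
    PhantomSpec,
    ShortcutSpec,
    TinyCNN,
    TrainConfig,
    auroc,
    predict_scores,
    sample_phantoms,
    shifted_saliency_stack,
    train,
)


def main():
    spec = PhantomSpec(
        label_names=("marker_driven",),
        lesions=(LesionSpec("disk", (12.0, 20.0), 0.0, (1, 1), 0.5),),
        shortcut=ShortcutSpec(corner="top_left", size=8, margin=4,
                              correlation=1.0, label_index=0),
    )
    images, labels, _ = sample_phantoms(spec, 500, seed=3, with_masks=False)
    enc = TinyCNN(16, 1, seed=1)
    cfg = TrainConfig(epochs=8, peak_lr=3e-2, weight_decay=1e-4, seed=4)
    enc, _ = train((images[:400], labels[:400]), enc, cfg)

    scores = predict_scores(enc, images[400:], 16)
    print(f"held-out AUROC = {auroc(scores[:, 0], labels[400:, 0]):.3f} "
          "-- looks like a great classifier...")

    pos = [i for i in range(400, 500) if labels[i, 0] == 1]
    in_marker = 0
    for i in pos:
        stack = shifted_saliency_stack(images[i], enc, 16, offset=16)
        y, x = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        in_marker += int(y // 16 == 0 and x // 16 == 0)
    print(f"...but the saliency argmax lands in the corner-marker patch for "
          f"{in_marker}/{len(pos)} positive images ({in_marker / len(pos):.0%}).")
    print("The 'pathology' the model found is the marker: shortcut exposed.")


if __name__ == "__main__":
    main()
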