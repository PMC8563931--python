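"""Cluster-based slide decisions and patient aggregation.

A slide is positive when at least four 4-connected patches exceed the patch
threshold; the continuous "bottleneck" slide score is the largest threshold
at which such a cluster survives.  A patient is positive iff any slide is.
"""

import numpy as np

from histossl import (InferenceConfig, SlideProbabilityMap, patient_decision,
                      patient_score, slide_decision, slide_score)


def pmap(prob):
    prob = np.asarray(prob, dtype=float)
    return SlideProbabilityMap(slide_id="demo", grid_shape=prob.shape,
                               prob=prob, tissue_mask=np.ones_like(prob,
                                                                   dtype=bool))


cfg = InferenceConfig()  # threshold 0.5, cluster size 4, 4-connectivity

run = np.zeros((6, 6))
run[2, 1:5] = 0.9  # four positives in a row
print("4-in-a-row  ->", "positive" if slide_decision(pmap(run), cfg)
      else "negative")

short = np.zeros((6, 6))
short[2, 1:4] = 0.9  # only three
print("3-in-a-row  ->", "positive" if slide_decision(pmap(short), cfg)
      else "negative")

block = np.full((8, 8), 0.1)
block[0, 0], block[0, 1], block[1, 0], block[1, 1] = 0.9, 0.8, 0.85, 0.95
score = slide_score(pmap(block), cfg)
print(f"2x2 block {{0.9, 0.8, 0.85, 0.95}} -> bottleneck score {score}")
# the weakest member of the best 4-cluster sets the score: 0.8 here

slide_scores = [slide_score(pmap(run), cfg), slide_score(pmap(short), cfg)]
print("patient score:", patient_score(slide_scores),
      "| decision:", "positive" if patient_decision(
          [slide_decision(pmap(run), cfg),
           slide_decision(pmap(short), cfg)]) else "negative")
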