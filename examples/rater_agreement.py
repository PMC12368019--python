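"""Blinded-rater video decisions and inter-rater agreement.

Two raters score each of ten command presentations yes/no; a trial is
positive if either rater saw a response, and a video is positive with at
least three positive trials.  Agreement is summarized by percent
agreement and Cohen's kappa.
"""

import numpy as np

from seeme.clinical import RaterRatings, rater_agreement, rater_video_decision

rater_a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
rater_b = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0], bool)

trial_pos, video_pos = rater_video_decision(RaterRatings(rater_a, rater_b))
print(f"positive trials (either-rater rule): {int(trial_pos.sum())}/10")
print(f"video decision: {'responsive' if video_pos else 'unresponsive'}")

agreement, kappa = rater_agreement(RaterRatings(rater_a, rater_b))
print(f"percent agreement: {agreement:.0%}, Cohen's kappa: {kappa:.2f}")
# The raters disagree on 2 of 10 trials (p_o = 0.8); with both marginals
# at 0.5, chance agreement is 0.5, giving kappa = 0.6.
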