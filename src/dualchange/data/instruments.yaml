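# Default instrument definitions.
#
# Cutoff bounds are inclusive lower bounds on the total (or subscale) score;
# the first bound of every cutoff table equals the scale minimum so that every
# valid score maps to exactly one label.
#
# The "high well-being" (mhcsf), "high life satisfaction" (swls) and BRS band
# bounds are documented implementer defaults traceable to the instrument
# manuals; override them via a user scales file if your study used different
# ones.  DASS-21 subscale sums are doubled (sum_times_two) so the severity
# bands below are the standard DASS-42-equivalent bands.

mhcsf:
  item_count: 14
  item_min: 0
  item_max: 5
  scoring_rule: sum
  direction: higher_is_better
  subscales:
    emotional: [1, 2, 3]
    social: [4, 5, 6, 7, 8]
    psychological: [9, 10, 11, 12, 13, 14]
  cutoffs:
    - [low, 0]
    - [high, 48]
  problematic_labels: [low]

swls:
  item_count: 5
  item_min: 1
  item_max: 7
  scoring_rule: sum
  direction: higher_is_better
  cutoffs:
    - [low, 5]
    - [high, 20]
  problematic_labels: [low]

dass21:
  item_count: 21
  item_min: 0
  item_max: 3
  scoring_rule: sum_times_two
  direction: lower_is_better
  subscales:
    depression: [3, 5, 10, 13, 16, 17, 21]
    anxiety: [2, 4, 7, 9, 15, 19, 20]
    stress: [1, 6, 8, 11, 12, 14, 18]
  subscale_cutoffs:
    depression:
      - [normal, 0]
      - [mild, 10]
      - [moderate, 14]
      - [severe, 21]
      - [extremely_severe, 28]
    anxiety:
      - [normal, 0]
      - [mild, 8]
      - [moderate, 10]
      - [severe, 15]
      - [extremely_severe, 20]
    stress:
      - [normal, 0]
      - [mild, 15]
      - [moderate, 19]
      - [severe, 26]
      - [extremely_severe, 34]
  problematic_labels: [mild, moderate, severe, extremely_severe]

brs:
  item_count: 6
  item_min: 1
  item_max: 5
  scoring_rule: mean
  direction: higher_is_better
  reverse_coded: [2, 4, 6]
  cutoffs:
    - [low, 1.0]
    - [normal, 3.0]
    - [high, 4.31]
  problematic_labels: [low]
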