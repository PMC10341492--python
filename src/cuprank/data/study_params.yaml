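# Group-level summaries (mean, SEM) of every quantitative endpoint of the
# 5-week cuprizone formulation-comparison study: 7 groups (untreated control
# plus six cuprizone formulations A-F), two coronal levels of the corpus
# callosum (region 215 = anterior commissure, lateral CC; region 265 =
# rostral hippocampus, medial CC).  These published group summaries
# parameterize the synthetic cohort generator; SEMs are converted to SDs
# with the source group size below.
#
# Units: *_OD in percent positive pixels; APP_DENSITY in spheroids per mm^2;
# LFB_SCORE on the ordinal 1 (complete demyelination) .. 4 (fully myelinated)
# scale; weights in grams.

design:
  groups: [control, cuprizone_A, cuprizone_B, cuprizone_C, cuprizone_D, cuprizone_E, cuprizone_F]
  n_per_group: 5
  source_n: 5          # 35 animals / 7 groups
  regions: [215, 265]

dose_schedule:
  start_concentration: 0.3      # percent w/w cuprizone in ground chow
  reduced_concentration: 0.275  # dose lowered once ~10% weight loss reached
  reduction_day: 16
  duration_days: 35

weights:
  start_mean_g: 22.0   # 6-week-old male C57BL/6 after one week acclimation
  start_sd_g: 0.5
  noise_sd_g: 0.3      # measurement-day jitter around the backbone
  final_g:             # end-of-study body weights
    control:     {mean: 26.7, sem: 1.0}
    cuprizone_A: {mean: 23.1, sem: 0.8}
    cuprizone_B: {mean: 23.7, sem: 0.8}
    cuprizone_C: {mean: 20.7, sem: 0.6}
    cuprizone_D: {mean: 21.0, sem: 0.5}
    cuprizone_E: {mean: 21.0, sem: 1.4}
    cuprizone_F: {mean: 20.8, sem: 1.2}

endpoints:
  - name: PLP_OD
    region: 265
    groups:
      control:     {mean: 96.8, sem: 0.5}
      cuprizone_A: {mean: 4.8,  sem: 1.8}
      cuprizone_B: {mean: 7.6,  sem: 2.7}
      cuprizone_C: {mean: 3.1,  sem: 0.4}
      cuprizone_D: {mean: 6.4,  sem: 1.1}
      cuprizone_E: {mean: 2.7,  sem: 1.1}
      cuprizone_F: {mean: 4.4,  sem: 1.9}
  - name: PLP_OD
    region: 215
    groups:
      control:     {mean: 85.0, sem: 2.3}
      cuprizone_A: {mean: 55.6, sem: 4.5}
      cuprizone_B: {mean: 58.9, sem: 6.2}
      cuprizone_C: {mean: 36.8, sem: 4.4}
      cuprizone_D: {mean: 48.2, sem: 5.4}
      cuprizone_E: {mean: 41.3, sem: 4.2}
      cuprizone_F: {mean: 37.7, sem: 2.3}
  - name: IBA1_OD
    region: 265
    groups:
      control:     {mean: 10.0, sem: 1.1}
      cuprizone_A: {mean: 51.9, sem: 5.3}
      cuprizone_B: {mean: 56.2, sem: 7.6}
      cuprizone_C: {mean: 64.3, sem: 6.6}
      cuprizone_D: {mean: 62.5, sem: 6.3}
      cuprizone_E: {mean: 70.1, sem: 3.8}
      cuprizone_F: {mean: 62.8, sem: 1.1}
  - name: IBA1_OD
    region: 215
    groups:
      control:     {mean: 11.2, sem: 1.0}
      cuprizone_A: {mean: 21.9, sem: 2.1}
      cuprizone_B: {mean: 23.5, sem: 1.5}
      cuprizone_C: {mean: 23.3, sem: 2.2}
      cuprizone_D: {mean: 21.1, sem: 1.3}
      cuprizone_E: {mean: 22.2, sem: 1.9}
      cuprizone_F: {mean: 27.2, sem: 2.2}
  - name: GFAP_OD
    region: 265
    groups:
      control:     {mean: 16.8, sem: 1.5}
      cuprizone_A: {mean: 82.4, sem: 3.3}
      cuprizone_B: {mean: 77.7, sem: 7.3}
      cuprizone_C: {mean: 74.4, sem: 4.6}
      cuprizone_D: {mean: 81.0, sem: 4.3}
      cuprizone_E: {mean: 66.2, sem: 5.2}
      cuprizone_F: {mean: 69.9, sem: 1.5}
  - name: GFAP_OD
    region: 215
    groups:
      control:     {mean: 29.7, sem: 1.3}
      cuprizone_A: {mean: 65.1, sem: 3.9}
      cuprizone_B: {mean: 60.1, sem: 2.4}
      cuprizone_C: {mean: 74.6, sem: 1.5}
      cuprizone_D: {mean: 68.2, sem: 4.6}
      cuprizone_E: {mean: 70.6, sem: 3.1}
      cuprizone_F: {mean: 69.6, sem: 2.6}
  - name: APP_DENSITY
    region: 265
    groups:
      control:     {mean: 23.6,  sem: 2.2}
      cuprizone_A: {mean: 609.6, sem: 91.1}
      cuprizone_B: {mean: 565.4, sem: 33.4}
      cuprizone_C: {mean: 595.1, sem: 61.8}
      cuprizone_D: {mean: 646.1, sem: 82.8}
      cuprizone_E: {mean: 702.0, sem: 46.4}
      cuprizone_F: {mean: 644.5, sem: 103.0}
  - name: APP_DENSITY
    region: 215
    groups:
      control:     {mean: 1.2,   sem: 0.8}
      cuprizone_A: {mean: 183.7, sem: 43.1}
      cuprizone_B: {mean: 177.6, sem: 55.9}
      cuprizone_C: {mean: 254.5, sem: 25.8}
      cuprizone_D: {mean: 169.1, sem: 13.2}
      cuprizone_E: {mean: 146.0, sem: 34.3}
      cuprizone_F: {mean: 209.4, sem: 33.5}
  - name: LFB_SCORE
    region: 265
    groups:
      control:     {mean: 3.9, sem: 0.1}
      cuprizone_A: {mean: 1.2, sem: 0.1}
      cuprizone_B: {mean: 1.0, sem: 0.0}
      cuprizone_C: {mean: 1.0, sem: 0.0}
      cuprizone_D: {mean: 1.1, sem: 0.1}
      cuprizone_E: {mean: 1.0, sem: 0.0}
      cuprizone_F: {mean: 1.0, sem: 0.0}
  - name: LFB_SCORE
    region: 215
    groups:
      control:     {mean: 4.0, sem: 0.0}
      cuprizone_A: {mean: 2.2, sem: 0.1}
      cuprizone_B: {mean: 2.5, sem: 0.3}
      cuprizone_C: {mean: 1.3, sem: 0.2}
      cuprizone_D: {mean: 1.3, sem: 0.2}
      cuprizone_E: {mean: 2.0, sem: 0.3}
      cuprizone_F: {mean: 1.4, sem: 0.2}

# Published group-mean cumulative ranks (Figure-7-style composite), kept for
# report comparison only -- never used by any computation.
reference_cumulative_ranks:
  region_265:
    control:     {mean: 12.8,  sem: 1.7}
    cuprizone_A: {mean: 93.0,  sem: 9.6}
    cuprizone_B: {mean: 82.6,  sem: 6.7}
    cuprizone_C: {mean: 105.4, sem: 8.9}
    cuprizone_D: {mean: 103.8, sem: 7.7}
    cuprizone_E: {mean: 103.8, sem: 7.7}
    cuprizone_F: {mean: 96.2,  sem: 6.3}
  region_215:
    control:     {mean: 12.2,  sem: 1.7}
    cuprizone_A: {mean: 61.0,  sem: 13.1}
    cuprizone_B: {mean: 60.0,  sem: 8.5}
    cuprizone_C: {mean: 94.6,  sem: 8.4}
    cuprizone_D: {mean: 78.6,  sem: 10.1}
    cuprizone_E: {mean: 84.6,  sem: 10.6}
    cuprizone_F: {mean: 106.3, sem: 8.2}
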