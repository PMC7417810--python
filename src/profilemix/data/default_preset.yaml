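# Default generating truth for the synthetic cohort.
#
# Eight profiles with the published prevalences; indicator distributions are
# artifact choices satisfying the qualitative profile descriptions (LP7 most
# severe, LP3 oldest/least severe, LP6 depression-dominant, LP8 youngest with
# the highest female and non-white rates).  Within-profile SDs are kept small
# so parameter-recovery tests at n=5000 are statistically feasible for the
# rarest profile (3.04%).
#
# change entries are [mean, sd] of the end-of-treatment score change drawn
# per scale; modality_change adds to the HI change mean for that modality.
labels: [LP1, LP2, LP3, LP4, LP5, LP6, LP7, LP8]
weights: [0.176, 0.241, 0.0304, 0.0492, 0.0958, 0.0821, 0.0964, 0.2291]
profiles:
  LP1:
    means: {phq: 8.5, gad: 7.5, wsas: 10.0, age: 27.0}
    sds: {phq: 1.6, gad: 1.6, wsas: 1.6, age: 1.6}
    rates: {phobia: 0.25, gender: 0.65, medication: 0.25, welfare: 0.10, ethnicity: 0.30}
    hi_prob: 0.20
    attrition: 0.16
    change:
      LI: {phq: [-4.5, 5.5], gad: [-4.0, 4.5]}
      HI: {phq: [-5.0, 5.5], gad: [-4.5, 4.5]}
    modality_change: {CBT: {phq: 0.0, gad: 0.0}, Counselling: {phq: -0.3, gad: -0.3}, IPT: {phq: 0.0, gad: 0.0}}
  LP2:
    means: {phq: 13.0, gad: 12.0, wsas: 13.0, age: 30.0}
    sds: {phq: 1.9, gad: 1.9, wsas: 1.9, age: 1.9}
    rates: {phobia: 0.20, gender: 0.65, medication: 0.20, welfare: 0.08, ethnicity: 0.30}
    hi_prob: 0.30
    attrition: 0.18
    change:
      LI: {phq: [-7.0, 6.0], gad: [-6.5, 5.5]}
      HI: {phq: [-7.5, 6.0], gad: [-7.0, 5.5]}
    modality_change: {CBT: {phq: 0.0, gad: 0.0}, Counselling: {phq: 0.0, gad: 0.0}, IPT: {phq: 0.0, gad: 0.0}}
  LP3:
    means: {phq: 7.0, gad: 6.0, wsas: 8.0, age: 67.0}
    sds: {phq: 0.7, gad: 0.7, wsas: 0.7, age: 0.7}
    rates: {phobia: 0.10, gender: 0.85, medication: 0.10, welfare: 0.08, ethnicity: 0.05}
    hi_prob: 0.15
    attrition: 0.13
    change:
      LI: {phq: [-3.0, 5.5], gad: [-2.5, 5.0]}
      HI: {phq: [-3.0, 5.5], gad: [-2.5, 5.0]}
    modality_change: {CBT: {phq: 0.0, gad: 0.0}, Counselling: {phq: 0.0, gad: 0.0}, IPT: {phq: 0.0, gad: 0.0}}
  LP4:
    means: {phq: 14.0, gad: 12.0, wsas: 22.0, age: 58.0}
    sds: {phq: 0.85, gad: 0.85, wsas: 0.85, age: 0.85}
    rates: {phobia: 0.80, gender: 0.70, medication: 0.15, welfare: 0.20, ethnicity: 0.08}
    hi_prob: 0.40
    attrition: 0.14
    change:
      LI: {phq: [-9.5, 5.5], gad: [-9.0, 4.5]}
      HI: {phq: [-8.0, 5.5], gad: [-7.5, 4.5]}
    modality_change: {CBT: {phq: -1.5, gad: -1.5}, Counselling: {phq: 1.0, gad: 1.0}, IPT: {phq: 0.0, gad: 0.0}}
  LP5:
    means: {phq: 17.0, gad: 15.0, wsas: 24.0, age: 45.0}
    sds: {phq: 1.2, gad: 1.2, wsas: 1.2, age: 1.2}
    rates: {phobia: 0.75, gender: 0.68, medication: 0.72, welfare: 0.55, ethnicity: 0.30}
    hi_prob: 0.60
    attrition: 0.25
    change:
      LI: {phq: [-6.5, 5.5], gad: [-6.0, 5.0]}
      HI: {phq: [-7.0, 5.5], gad: [-6.5, 5.0]}
    modality_change: {CBT: {phq: -1.5, gad: -1.5}, Counselling: {phq: 0.5, gad: 0.5}, IPT: {phq: 0.0, gad: 0.0}}
  LP6:
    means: {phq: 19.0, gad: 12.0, wsas: 22.0, age: 40.0}
    sds: {phq: 1.1, gad: 1.1, wsas: 1.1, age: 1.1}
    rates: {phobia: 0.55, gender: 0.60, medication: 0.70, welfare: 0.55, ethnicity: 0.30}
    hi_prob: 0.70
    attrition: 0.28
    change:
      LI: {phq: [-6.0, 7.0], gad: [-3.5, 6.5]}
      HI: {phq: [-6.5, 7.0], gad: [-4.0, 6.5]}
    modality_change: {CBT: {phq: 0.0, gad: 0.0}, Counselling: {phq: 0.3, gad: 0.3}, IPT: {phq: 0.0, gad: 0.0}}
  LP7:
    means: {phq: 23.0, gad: 18.0, wsas: 30.0, age: 44.0}
    sds: {phq: 1.2, gad: 1.2, wsas: 1.2, age: 1.2}
    rates: {phobia: 0.80, gender: 0.66, medication: 0.80, welfare: 0.60, ethnicity: 0.35}
    hi_prob: 0.85
    attrition: 0.35
    change:
      LI: {phq: [-9.0, 5.5], gad: [-8.0, 4.5]}
      HI: {phq: [-11.0, 5.5], gad: [-9.5, 4.5]}
    modality_change: {CBT: {phq: 0.0, gad: 0.0}, Counselling: {phq: 0.0, gad: 0.0}, IPT: {phq: 0.0, gad: 0.0}}
  LP8:
    means: {phq: 16.0, gad: 14.0, wsas: 18.0, age: 24.0}
    sds: {phq: 1.85, gad: 1.85, wsas: 1.85, age: 1.85}
    rates: {phobia: 0.55, gender: 0.90, medication: 0.50, welfare: 0.26, ethnicity: 0.75}
    hi_prob: 0.50
    attrition: 0.22
    change:
      LI: {phq: [-7.5, 5.5], gad: [-7.0, 4.5]}
      HI: {phq: [-8.5, 5.5], gad: [-8.0, 4.5]}
    modality_change: {CBT: {phq: -1.2, gad: -1.2}, Counselling: {phq: 0.5, gad: 0.5}, IPT: {phq: 0.0, gad: 0.0}}
years:
  "2013/14": 0.2
  "2014/15": 0.2
  "2015/16": 0.2
  "2016/17": 0.2
  "2017/18": 0.2
li_modalities: {GSH: 0.7, cCBT: 0.3}
hi_modalities: {CBT: 0.55, Counselling: 0.35, IPT: 0.10}
sessions: {LI: 5.0, HI: 10.0}
step_up_prob: 0.10
second_modality_prob: 0.15
even_split_prob: 0.05
missing_rate: 0.02
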