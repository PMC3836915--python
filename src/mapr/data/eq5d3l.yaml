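# EQ-5D-like descriptive system: 5 attributes x 3 ordered levels,
# level 1 best. Synthetic stand-in phrased after the familiar wording.
attributes:
  - name: mobility
    levels: ["no problems walking", "some problems walking", "confined to bed"]
  - name: self_care
    levels: ["no problems with self-care", "some problems washing or dressing", "unable to wash or dress"]
  - name: usual_activities
    levels: ["no problems with usual activities", "some problems with usual activities", "unable to perform usual activities"]
  - name: pain_discomfort
    levels: ["no pain or discomfort", "moderate pain or discomfort", "extreme pain or discomfort"]
  - name: anxiety_depression
    levels: ["not anxious or depressed", "moderately anxious or depressed", "extremely anxious or depressed"]
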