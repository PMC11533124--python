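# Age-specific standard energy levels (kcal/d) used for energy adjustment
# of reported intakes.  Bands partition completed ages 0-19.
- {band: "<1",   age_lo: 0,  age_hi: 0,  kcal: 700}
- {band: "1-<2", age_lo: 1,  age_hi: 1,  kcal: 1000}
- {band: "2-5",  age_lo: 2,  age_hi: 5,  kcal: 1300}
- {band: "6-10", age_lo: 6,  age_hi: 10, kcal: 1700}
- {band: "11-19", age_lo: 11, age_hi: 19, kcal: 2000}
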