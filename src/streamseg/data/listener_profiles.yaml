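# Listener profiles: A/B noise-band assignment per spectral-separation level.
#
# NH: B fixed at 1803 Hz; A at 1803 / 3022 / 6665 Hz for none / moderate /
# large separation (0.75 and 1.89 octaves).
#
# CI1-CI6: per-user band center frequencies and clinical-MAP electrode
# numbers for the B band and for the A band at the moderate and large
# separations.  At the "none" level A and B are identical.  Electrode
# numbering: 1 = most basal.
NH:
  group: NH
  bands:
    none:     {a_cf: 1803, b_cf: 1803}
    moderate: {a_cf: 3022, b_cf: 1803}
    large:    {a_cf: 6665, b_cf: 1803}
CI1:
  group: CI
  brand: Cochlear
  bands:
    none:     {a_cf: 1808, b_cf: 1808, a_electrode: 11, b_electrode: 11}
    moderate: {a_cf: 2927, b_cf: 1808, a_electrode: 8,  b_electrode: 11}
    large:    {a_cf: 6418, b_cf: 1808, a_electrode: 2,  b_electrode: 11}
CI2:
  group: CI
  brand: Cochlear
  bands:
    none:     {a_cf: 1683, b_cf: 1683, a_electrode: 12, b_electrode: 12}
    moderate: {a_cf: 2871, b_cf: 1683, a_electrode: 8,  b_electrode: 12}
    large:    {a_cf: 6485, b_cf: 1683, a_electrode: 2,  b_electrode: 12}
CI3:
  group: CI
  brand: MED-EL
  bands:
    none:     {a_cf: 1632, b_cf: 1632, a_electrode: 7,  b_electrode: 7}
    moderate: {a_cf: 3064, b_cf: 1632, a_electrode: 10, b_electrode: 7}
    large:    {a_cf: 7352, b_cf: 1632, a_electrode: 12, b_electrode: 7}
CI4:
  group: CI
  brand: Cochlear
  bands:
    none:     {a_cf: 1741, b_cf: 1741, a_electrode: 11, b_electrode: 11}
    moderate: {a_cf: 3092, b_cf: 1741, a_electrode: 7,  b_electrode: 11}
    large:    {a_cf: 6828, b_cf: 1741, a_electrode: 2,  b_electrode: 11}
CI5:
  group: CI
  brand: Cochlear
  bands:
    none:     {a_cf: 1683, b_cf: 1683, a_electrode: 12, b_electrode: 12}
    moderate: {a_cf: 2871, b_cf: 1683, a_electrode: 8,  b_electrode: 12}
    large:    {a_cf: 6485, b_cf: 1683, a_electrode: 2,  b_electrode: 12}
CI6:
  group: CI
  brand: Cochlear
  bands:
    none:     {a_cf: 1683, b_cf: 1683, a_electrode: 12, b_electrode: 12}
    moderate: {a_cf: 2871, b_cf: 1683, a_electrode: 8,  b_electrode: 12}
    large:    {a_cf: 6485, b_cf: 1683, a_electrode: 2,  b_electrode: 12}
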