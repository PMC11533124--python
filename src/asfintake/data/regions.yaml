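# Country (ISO3) -> superregion lookup for the 7 world superregions used in
# the nested hierarchy and reporting.  This is editable configuration, not a
# complete gazetteer: extend it for countries you ingest.  Codes beginning
# with "X" are reserved for synthetic worlds and are assigned at run time.
regions:
  - South Asia
  - Southeast and East Asia
  - Central/Eastern Europe and Central Asia
  - Middle East and Northern Africa
  - Latin America and the Caribbean
  - sub-Saharan Africa
  - High-income countries
countries:
  AFG: South Asia
  BGD: South Asia
  BTN: South Asia
  IND: South Asia
  NPL: South Asia
  PAK: South Asia
  LKA: South Asia
  CHN: Southeast and East Asia
  IDN: Southeast and East Asia
  JPN: High-income countries
  KHM: Southeast and East Asia
  KOR: High-income countries
  LAO: Southeast and East Asia
  MMR: Southeast and East Asia
  MNG: Southeast and East Asia
  MYS: Southeast and East Asia
  PHL: Southeast and East Asia
  PNG: Southeast and East Asia
  THA: Southeast and East Asia
  VNM: Southeast and East Asia
  ARM: Central/Eastern Europe and Central Asia
  AZE: Central/Eastern Europe and Central Asia
  BLR: Central/Eastern Europe and Central Asia
  GEO: Central/Eastern Europe and Central Asia
  KAZ: Central/Eastern Europe and Central Asia
  KGZ: Central/Eastern Europe and Central Asia
  MDA: Central/Eastern Europe and Central Asia
  RUS: Central/Eastern Europe and Central Asia
  TJK: Central/Eastern Europe and Central Asia
  TKM: Central/Eastern Europe and Central Asia
  UKR: Central/Eastern Europe and Central Asia
  UZB: Central/Eastern Europe and Central Asia
  BGR: Central/Eastern Europe and Central Asia
  HRV: Central/Eastern Europe and Central Asia
  LVA: Central/Eastern Europe and Central Asia
  MNE: Central/Eastern Europe and Central Asia
  ROU: Central/Eastern Europe and Central Asia
  SRB: Central/Eastern Europe and Central Asia
  DZA: Middle East and Northern Africa
  EGY: Middle East and Northern Africa
  IRN: Middle East and Northern Africa
  IRQ: Middle East and Northern Africa
  JOR: Middle East and Northern Africa
  LBN: Middle East and Northern Africa
  MAR: Middle East and Northern Africa
  SAU: Middle East and Northern Africa
  TUN: Middle East and Northern Africa
  TUR: Middle East and Northern Africa
  YEM: Middle East and Northern Africa
  ARG: Latin America and the Caribbean
  BOL: Latin America and the Caribbean
  BRA: Latin America and the Caribbean
  CHL: Latin America and the Caribbean
  COL: Latin America and the Caribbean
  CRI: Latin America and the Caribbean
  CUB: Latin America and the Caribbean
  DOM: Latin America and the Caribbean
  ECU: Latin America and the Caribbean
  GTM: Latin America and the Caribbean
  HTI: Latin America and the Caribbean
  HND: Latin America and the Caribbean
  JAM: Latin America and the Caribbean
  MEX: Latin America and the Caribbean
  NIC: Latin America and the Caribbean
  PAN: Latin America and the Caribbean
  PER: Latin America and the Caribbean
  PRY: Latin America and the Caribbean
  SLV: Latin America and the Caribbean
  URY: Latin America and the Caribbean
  VEN: Latin America and the Caribbean
  AGO: sub-Saharan Africa
  BEN: sub-Saharan Africa
  BFA: sub-Saharan Africa
  CIV: sub-Saharan Africa
  CMR: sub-Saharan Africa
  COD: sub-Saharan Africa
  ETH: sub-Saharan Africa
  GHA: sub-Saharan Africa
  KEN: sub-Saharan Africa
  MDG: sub-Saharan Africa
  MLI: sub-Saharan Africa
  MOZ: sub-Saharan Africa
  MWI: sub-Saharan Africa
  NER: sub-Saharan Africa
  NGA: sub-Saharan Africa
  RWA: sub-Saharan Africa
  SEN: sub-Saharan Africa
  SLE: sub-Saharan Africa
  TZA: sub-Saharan Africa
  UGA: sub-Saharan Africa
  ZAF: sub-Saharan Africa
  ZMB: sub-Saharan Africa
  ZWE: sub-Saharan Africa
  AUS: High-income countries
  AUT: High-income countries
  BEL: High-income countries
  CAN: High-income countries
  CHE: High-income countries
  DEU: High-income countries
  DNK: High-income countries
  ESP: High-income countries
  FIN: High-income countries
  FRA: High-income countries
  GBR: High-income countries
  GRC: High-income countries
  IRL: High-income countries
  ISR: High-income countries
  ITA: High-income countries
  NLD: High-income countries
  NOR: High-income countries
  NZL: High-income countries
  POL: High-income countries
  PRT: High-income countries
  SWE: High-income countries
  USA: High-income countries
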