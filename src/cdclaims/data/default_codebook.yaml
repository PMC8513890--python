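# Default codebook for the Crohn's disease case-identification rules.
#
# Diagnosis prefixes are real ICD-10 chapter prefixes; the prescription and
# surgery entries are PLACEHOLDER codes named after the CD drug classes
# (mesalazine, thiopurines, elemental diet, budesonide, biologics) and
# CD-typical operations.  Replace them with the national receipt codes of the
# target claims database before running on real data.
cd_dx_prefixes:
  - K50            # Crohn's disease [regional enteritis]
excl_dx_prefixes:
  - K51            # ulcerative colitis
  - M35            # Behçet's disease and other systemic connective-tissue involvement
cd_rx_codes:
  - RX-MESALAZINE
  - RX-AZATHIOPRINE
  - RX-MERCAPTOPURINE
  - RX-ELEMENTAL-DIET
  - RX-BUDESONIDE
  - RX-INFLIXIMAB
  - RX-INFLIXIMAB-BS
  - RX-ADALIMUMAB
  - RX-USTEKINUMAB
  - RX-VEDOLIZUMAB
cd_pr_codes:
  - PR-INTESTINAL-RESECTION
  - PR-STRICTUREPLASTY
  - PR-ANAL-FISTULA-REPAIR
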