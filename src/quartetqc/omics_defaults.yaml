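# Default per-omics thresholds.
#
# cv_cutoff:            intra-batch replicate CV above which a feature is dropped
# def_p_cutoff:         Welch two-sided P cutoff for differential features
# def_lfc_cutoff:       |log2 fold change| cutoff for differential features
# batch_presence_rate:  fraction of batches a feature must be quantifiable in
#                       before entering the cross-batch consensus vote
# detection_rate:       multi-batch detection filter (keep if detected in
#                       strictly more than this fraction of samples)
# floor_value:          linear-scale offset added before log2 transform
#                       (null = no flooring for that omics type)

methylation:
  cv_cutoff: 0.15
  def_p_cutoff: 0.05
  def_lfc_cutoff: 2.0
  batch_presence_rate: 0.7
  detection_rate: 0.9
  floor_value: null

mirna:
  cv_cutoff: 0.3
  def_p_cutoff: 0.05
  def_lfc_cutoff: 0.5
  batch_presence_rate: 0.7
  detection_rate: 0.9
  floor_value: 0.01

rna:
  cv_cutoff: 0.3
  def_p_cutoff: 0.05
  def_lfc_cutoff: 0.5
  batch_presence_rate: 0.7
  detection_rate: 0.9
  floor_value: 0.01

protein:
  cv_cutoff: 0.3
  def_p_cutoff: 0.05
  def_lfc_cutoff: 0.5
  batch_presence_rate: 0.3
  detection_rate: 0.9
  floor_value: null

metabolite:
  cv_cutoff: 0.3
  def_p_cutoff: 0.05
  def_lfc_cutoff: 0.5
  batch_presence_rate: 0.3
  detection_rate: 0.9
  floor_value: null

dna:
  cv_cutoff: 0.3
  def_p_cutoff: 0.05
  def_lfc_cutoff: 0.5
  batch_presence_rate: 0.7
  detection_rate: 0.9
  floor_value: null
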