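# Clinical RTSTRUCT name -> tissue-library name.
# Lookup is tried verbatim, then lower-cased.
Lung_L: lungs
Lung_R: lungs
lung_l: lungs
lung_r: lungs
lung: lungs
lungs: lungs
Breast_L: breast
Breast_R: breast
breast: breast
SpinalCord: spinal_cord
spinal cord: spinal_cord
spinal_cord: spinal_cord
cord: spinal_cord
Esophagus: oesophagus
esophagus: oesophagus
oesophagus: oesophagus
Heart: heart
heart: heart
GreatVessels: vessels
great vessels: vessels
vessels: vessels
Liver: liver
liver: liver
Stomach: stomach
stomach: stomach
Spleen: spleen
spleen: spleen
Thyroid: thyroid
thyroid: thyroid
Pharynx: pharynx
pharynx: pharynx
Bone: bone
bone: bone
Body: soft_tissue
body: soft_tissue
External: soft_tissue
soft tissue: soft_tissue
soft_tissue: soft_tissue
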