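# Head-and-neck OAR label registry: pattern <TAB> anatomic name
# "[l,r]" marks a bilateral organ pair expanding to _l and _r labels.
brachial_plex_[l,r]	Brachial plexus nerve
brain	Brain
brain_stem	Brainstem
carotid_artery_[l,r]	Carotid artery
cochlea_[l,r]	Cochlea
constrictors_p	Pharyngeal constrictor muscle
cord	Spinal cord
crico_p_inlet	Cricopharyngeal inlet muscle
esophagus	Esophagus
esophagus_cerv	Cervical esophagus
ext_aud_canal_[l,r]	External auditory canal
eye_[l,r]	Eye
lacrimal_[l,r]	Lacrimal gland
larynx	Larynx
lens_[l,r]	Lens
lips	Lips
lung_[l,r]	Lung
mandible	Mandible
mastoid_[l,r]	Mastoid air cells
nasal_cavity	Nasal cavity (region)
optic_nrv_[l,r]	Optic nerve
oral_cavity	Oral cavity (region)
parotid_[l,r]	Parotid gland
pituitary	Pituitary gland
retina_[l,r]	Retina
semi_cir_canal_[l,r]	Semicircular canal
sub_mandib_[l,r]	Submandibular gland
thyroid	Thyroid gland
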