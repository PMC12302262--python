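term,group
taste disorder,taste
ageusia,taste
oral herpes,oral_mucosa
dysgeusia,taste
paraesthesia oral,sensation
hypoaesthesia oral,sensation
swollen tongue,tongue
dry mouth,salivary_glands
lip swelling,lips
aphthous ulcer,oral_mucosa
oral disorder,oral_mucosa
tongue disorder,tongue
stomatitis,oral_mucosa
hypogeusia,taste
mouth swelling,oral_mucosa
hyper salivation,salivary_glands
glossodynia,tongue
oral mucosal erythema,oral_mucosa
sialadenitis,salivary_glands
tongue coated,tongue
lip oedema,lips
tongue paralysis,tongue
anaesthesia oral,sensation
oral mucosal blister,oral_mucosa
dental discomfort,dentition
oral dysaesthesia,sensation
cheilitis,lips
noninfective sialoadenitis,salivary_glands
tongue movement disturbance,tongue
oral candidiasis,oral_mucosa
lip dry,lips
glossitis,tongue
trichoglossia,tongue
palatal swelling,palate
aptyalism,salivary_glands
tongue blistering,tongue
tongue eruption,tongue
tongue oedema,tongue
oral mucosa erosion,oral_mucosa
oral pruritus,oral_mucosa
perioral dermatitis,oral_mucosa
hyperaesthesia teeth,dentition
tongue discolouration,tongue
oral lichen planus,oral_mucosa
oral fungal infection,oral_mucosa
oral mucosal eruption,oral_mucosa
salivary gland enlargement,salivary_glands
saliva changes,salivary_glands
angular cheilitis,lips
lip blister,lips
circumoral swelling,oral_mucosa
tongue dry,tongue
tongue erythema,tongue
tongue ulceration,palate
palatal disorder,palate
lip disorder,lips
lip erythema,lips
lip pain,lips
chapped lips,lips
dental paraesthesia,dentition
salivary gland pain,salivary_glands
stiff tongue,tongue
tongue exfoliation,tongue
tongue pruritus,tongue
tongue spasm,tongue
oral lichenoid reaction,oral_mucosa
oral mucosal roughening,oral_mucosa
lip erosion,lips
salivary gland disorder,salivary_glands
salivary gland mass,salivary_glands
salivary gland calculus,salivary_glands
tongue papillae hypertrophy,tongue
macroglossia,tongue
tongue fungal infection,tongue
circumoral oedema,oral_mucosa
oral mucosal exfoliation,oral_mucosa
leukoplakia oral,oral_mucosa
palatal oedema,palate
lip exfoliation,lips
hypoesthesia teeth,dentition
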