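name	sequence	staple_i	n_positive
wt_ASC_PYD	T A E E L K K F K L K L L S V	-	4
wts_ASC_PYD#1	T A E E * K K F K L K * L S V	5	4
ms_ASC_PYD#2	T A R E * K K A K F K * E S V	5	5
ms_ASC_PYD#3	T A R V * K K A K F K * E S V	5	5
ms_ASC_PYD#4	T A R A * K V A K F K * E S V	5	4
ms_ASC_PYD#5	T A R A * K L A K I K * E S V	5	4
ms_ASC_PYD#6	R A * K K A K I K * E S V	3	5
wt_NLRP3_PYD	V D L K K F K M H L E D Y	-	4
m_NLRP3_PYD	V D L K K A K F H L E D Y	-	4
ms_NLRP3_PYD	V D * K K A K F H * E D Y	3	4
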