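# Context templates for synthetic clinical sentences.
# One template per line; "{M}" marks a regimen-mention slot; "#" lines and
# blank lines are ignored.  Rendered sentences are short bilingual
# narratives (roughly 10-120 characters) mixing Chinese clinical filler
# with English regimen surface forms.
入院后完善相关检查，无化疗禁忌，给予{M}方案辅助化疗，过程顺利。
患者于外院行{M}方案化疗4周期，耐受可，无明显骨髓抑制。
术后病理回报后，拟行{M}方案化疗，患者及家属表示知情同意。
今日行{M}方案化疗第2周期，化疗过程顺利，无明显不良反应。
患者诉恶心、呕吐，予甲磺酸多拉司琼注射液对症处理后好转。
复查血常规未见明显异常，继续观察，暂不调整治疗方案。
乳腺癌术后，给予{M}方案化疗，化疗后出现轻度脱发，余无特殊。
患者因左乳肿物入院，完善检查后行{M}方案新辅助化疗。
经多学科会诊讨论，建议{M}方案化疗，序贯放疗。
化疗方案由{M}调整为{M}，患者耐受可，生命体征平稳。
前期行{M}方案治疗，评估病情进展后改为{M}方案继续治疗。
予{M}方案化疗，同时予保肝、止吐等对症支持治疗。
患者既往行{M}方案化疗6周期，本次入院复查评估疗效。
查体：双乳对称，术区愈合良好，拟继续{M}方案化疗。
After admission, {M} chemotherapy was given without obvious side effects.
The patient received {M} regimen and tolerated it well.
Adjuvant chemotherapy with {M} was started after surgery.
患者一般情况可，今日予{M}方案化疗，过程顺利，安返病房。
入院诊断：右乳浸润性导管癌。治疗：{M}方案化疗。
患者化疗后白细胞减低，予升白细胞治疗，好转后出院。
本周期采用{M}方案，下周期拟换用{M}方案，具体待评估。
患者入院后精神可，饮食睡眠尚可，二便正常。
予{M}方案行术前新辅助化疗，肿块较前缩小，疗效评价部分缓解。
化疗期间监测肝肾功能，未见明显异常，继续{M}方案治疗。
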