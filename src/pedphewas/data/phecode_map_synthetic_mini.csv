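icd9,phecode,description,exclude_lo,exclude_hi,category
008.45,008,Intestinal infection,1,9.99,infectious diseases
008.8,008,Intestinal infection,1,9.99,infectious diseases
009.0,008,Intestinal infection,1,9.99,infectious diseases
041.00,041,Bacterial infection,41,41.99,infectious diseases
041.10,041,Bacterial infection,41,41.99,infectious diseases
041.9,041,Bacterial infection,41,41.99,infectious diseases
204.00,204.1,Lymphoid leukemia,199,208.99,neoplasms
204.10,204.1,Lymphoid leukemia,199,208.99,neoplasms
216.5,216,Benign neoplasm of skin,216,216.99,neoplasms
216.9,216,Benign neoplasm of skin,216,216.99,neoplasms
250.01,250.1,Type 1 diabetes,249,250.99,endocrine/metabolic
250.11,250.1,Type 1 diabetes,249,250.99,endocrine/metabolic
250.91,250.1,Type 1 diabetes,249,250.99,endocrine/metabolic
250.00,250.2,Type 2 diabetes,249,250.99,endocrine/metabolic
250.10,250.2,Type 2 diabetes,249,250.99,endocrine/metabolic
790.21,250.4,Abnormal glucose,249,250.99,endocrine/metabolic
790.29,250.4,Abnormal glucose,249,250.99,endocrine/metabolic
244.8,244,Hypothyroidism,240,246.99,endocrine/metabolic
244.9,244,Hypothyroidism,240,246.99,endocrine/metabolic
245.1,245.2,Thyroiditis,240,246.99,endocrine/metabolic
245.2,245.2,Thyroiditis,240,246.99,endocrine/metabolic
288.3,288.3,Eosinophilia,288,288.99,hematopoietic
288.4,288.3,Eosinophilia,288,288.99,hematopoietic
280.9,285,Anemia,280,285.99,hematopoietic
285.8,285,Anemia,280,285.99,hematopoietic
285.9,285,Anemia,280,285.99,hematopoietic
296.20,296.2,Depression,295,302.99,mental disorders
296.30,296.2,Depression,295,302.99,mental disorders
311,296.2,Depression,295,302.99,mental disorders
315.31,315.2,Speech and language disorder,315,315.99,mental disorders
315.32,315.2,Speech and language disorder,315,315.99,mental disorders
315.39,315.2,Speech and language disorder,315,315.99,mental disorders
317,315.3,Mental retardation,315,319.99,mental disorders
318.0,315.3,Mental retardation,315,319.99,mental disorders
318.1,315.3,Mental retardation,315,319.99,mental disorders
319,315.3,Mental retardation,315,319.99,mental disorders
299.00,313.3,Autism,313,313.99,mental disorders
299.01,313.3,Autism,313,313.99,mental disorders
299.80,313.2,Pervasive developmental disorder,313,313.99,mental disorders
299.90,313.2,Pervasive developmental disorder,313,313.99,mental disorders
299.91,313.2,Pervasive developmental disorder,313,313.99,mental disorders
345.10,345,Epilepsy,345,345.99,neurological
345.90,345,Epilepsy,345,345.99,neurological
343.0,343,Cerebral palsy,342,344.99,neurological
343.9,343,Cerebral palsy,342,344.99,neurological
382.00,381.1,Suppurative otitis media,380,384.99,sense organs
382.4,381.1,Suppurative otitis media,380,384.99,sense organs
382.9,381.1,Suppurative otitis media,380,384.99,sense organs
364.00,364.1,Uveitis,360,369.99,sense organs
364.3,364.1,Uveitis,360,369.99,sense organs
367.0,367.1,Myopia,367,367.99,sense organs
367.1,367.1,Myopia,367,367.99,sense organs
410.90,411.2,Myocardial infarction,410,414.99,circulatory system
412,411.2,Myocardial infarction,410,414.99,circulatory system
411.1,411.8,Ischemic heart disease,410,414.99,circulatory system
413.9,411.8,Ischemic heart disease,410,414.99,circulatory system
414.9,411.8,Ischemic heart disease,410,414.99,circulatory system
401.1,401.1,Hypertension,401,405.99,circulatory system
401.9,401.1,Hypertension,401,405.99,circulatory system
493.00,495,Asthma,490,496.99,respiratory
493.90,495,Asthma,490,496.99,respiratory
493.92,495,Asthma,490,496.99,respiratory
786.07,512.8,Wheezing,490,519.99,respiratory
786.09,512.8,Wheezing,490,519.99,respiratory
477.0,476,Allergic rhinitis,470,478.99,respiratory
477.8,476,Allergic rhinitis,470,478.99,respiratory
477.9,476,Allergic rhinitis,470,478.99,respiratory
555.0,555.1,Crohn's disease,555,558.99,digestive
555.1,555.1,Crohn's disease,555,558.99,digestive
555.9,555.1,Crohn's disease,555,558.99,digestive
556.0,555.2,Ulcerative colitis,555,558.99,digestive
556.9,555.2,Ulcerative colitis,555,558.99,digestive
530.13,530.13,Eosinophilic esophagitis,530,530.99,digestive
530.19,530.13,Eosinophilic esophagitis,530,530.99,digestive
530.11,530.11,Reflux esophagitis,530,530.99,digestive
530.81,530.11,Reflux esophagitis,530,530.99,digestive
599.0,591,Urinary tract infection,590,599.99,genitourinary
590.10,591,Urinary tract infection,590,599.99,genitourinary
580.9,580,Nephritis,580,589.99,genitourinary
583.9,580,Nephritis,580,589.99,genitourinary
691.0,939.1,Atopic dermatitis,939,939.99,dermatologic
691.8,939.1,Atopic dermatitis,939,939.99,dermatologic
696.0,696.4,Psoriasis,696,696.99,dermatologic
696.1,696.4,Psoriasis,696,696.99,dermatologic
995.60,930.0,Food allergy,930,930.99,dermatologic
995.61,930.0,Food allergy,930,930.99,dermatologic
693.1,930.0,Food allergy,930,930.99,dermatologic
714.30,714.1,Juvenile rheumatoid arthritis,714,714.99,musculoskeletal
714.31,714.1,Juvenile rheumatoid arthritis,714,714.99,musculoskeletal
714.32,714.1,Juvenile rheumatoid arthritis,714,714.99,musculoskeletal
714.33,714.1,Juvenile rheumatoid arthritis,714,714.99,musculoskeletal
714.0,714,Rheumatoid arthritis,714,714.99,musculoskeletal
714.2,714,Rheumatoid arthritis,714,714.99,musculoskeletal
715.90,715,Osteoarthrosis,715,716.99,musculoskeletal
715.98,715,Osteoarthrosis,715,716.99,musculoskeletal
758.0,758,Chromosomal anomalies,758,758.99,congenital anomalies
758.9,758,Chromosomal anomalies,758,758.99,congenital anomalies
749.00,749,Cleft palate,749,749.99,congenital anomalies
749.10,749,Cleft palate,749,749.99,congenital anomalies
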