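# 32-patient 46,XY DSD cohort with uninformative exome sequencing.
# category: 1 = 46,XY women with gonadal dysgenesis; 2 = 46,XY females;
# 3 = 46,XY with ambiguous genitalia; 4 = 46,XY males with hypogonadism.
patient_id	category	karyotype	dsd_category	clinical_features
RDSD002	1	46,XY	46,XY female, CGD
RDSD003	1	46,XY	46,XY female, PGD	No uterus; Fallopian tubes present; short vagina; very low T and undetectable estradiol; gonads not found
RDSD004	1	46,XY	46,XY female, GD
RDSD006	2	46,XY	46,XY female	Amelia (missing limbs)
RDSD007	1	46,XY	46,XY female, GD	Adrenal rests
RDSD010	2	46,XY	46,XY female	Clitoromegaly
RDSD011	2	46,XY	46,XY female	Short stature
RDSD012	2	46,XY	46,XY female	Kidney disease; possible Denys-Drash syndrome
RDSD013	1	46,XY	46,XY female, CGD	Normal uterus and Fallopian tubes; streak gonads
RDSD018	3	46,XY	46,XY ambiguous genitalia	Partial fusion of labioscrotal folds; small phallus; penoscrotal hypospadias
RDSD020	3	46,XY	46,XY ambiguous genitalia	Developmental delay; agenesis of corpus callosum
RDSD021	3	46,XY	46,XY ambiguous genitalia	Adrenal hypoplasia congenita; dysmorphic features
RDSD022	3	46,XY	46,XY ambiguous genitalia	Microcephaly; intestinal dysmotility; optic nerve hypoplasia
RDSD025	4	46,XY	46,XY male, micropenis/cryptochidism	Severe growth and developmental retardation; testes not seen by ultrasound
CDSD029	4	46,XY	46,XY male, hypospadias
CDSD030	2	46,XY	46,XY female	Large clitoris; no uterus or vaginal opening; inguinal testes
CDSD031	3	46,XY	46,XY ambiguous genitalia, CGD	Abdominal gonads with no oocytes; no seminiferous tubules; no clitoromegaly; posterior fusion of labia; urogenital sinus
CDSD032	2	46,XY	46,XY female	Inguinal testes w/ immature seminiferous tubules; no uterus or Fallopian tubes; deafness; impaired cognition
CDSD034	3	46,XY	46,XY ambiguous genitalia	Undescended testes; bifid scrotum; hypospadias
CDSD036	3	46,XY	46,XY ambiguous genitalia	Bilateral descended testes; midshaft hypospadias; chordee
CDSD039	4	46,XY	46,XY male, micropenis	No uterus or ovaries per ultrasound; ambiguous genitalia; undervirilization
RDSD041	2	46,XY	46,XY female	Complete androgen insensitivity syndrome
RDSD042	4	46,XY	46,XY male, hypospadias
RDSD043	1	46,XY	46,XY female, GD
RDSD044	4	46,XY	46,XY male, anorchia	Congenital bilateral anorchia; fully formed scrotum; definite penis (mildly shortened); no hypospadias; responsive to testosterone
RDSD045	4	46,XY	46,XY male, hypospadias/cryptorchidism	Azoospermia; high T levels
RDSD046	2	46,XY	46,XY female	Multiple congenital anomalies; no uterus; abdominal gonads—testes
RDSD047	4	46,XY	46,XY male, microphallus	Hypogonadism; hypospadias
RDSD048	4	46,XY	46,XY male, micropenis
RDSD049	4	46,XY	46,XY male, hypospadias
CDSD050	4	46,XY	46,XY male, hypospadias	Chordee; bifid scrotum; cryptorchidism
CDSD051	2	46,XY	46,XY female	Growth delay; short stature
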